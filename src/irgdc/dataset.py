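"""Labeled expression matrices and delimited-text I/O.

The universal input of the package is an :class:`ExpressionDataset`: a
genes x samples matrix of continuous expression values plus a class label
per sample.  Matrices are exchanged as delimited text (TSV or CSV) with a
single header row of sample identifiers and one row per gene; labels come
from a separate two-column (sample_id, class) file.  No normalisation,
log transform or imputation is applied on load: missing or non-numeric
cells are an error, because every downstream statistic would silently
change under imputation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "load_dataset",
    "read_labels",
    "write_dataset",
    "write_ranked_list",
    "read_ranked_list",
    "write_selection_trace",
    "write_predictions",
]


@dataclass
class ExpressionDataset:
    """A labeled genes x samples expression matrix.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, one per matrix row.
    sample_ids : sequence of str
        Unique sample identifiers, one per matrix column.
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values.
    labels : sequence of str
        Class label of each sample.  Classes are treated as opaque
        strings; the internal class order is the sorted order of the
        distinct label strings, fixed at construction, which makes every
        downstream tie-break deterministic.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    labels: np.ndarray
    classes_: np.ndarray = field(init=False, repr=False)
    y_: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.labels = np.asarray(self.labels, dtype=str)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        p, n = self.values.shape
        if len(self.gene_ids) != p or len(self.sample_ids) != n:
            raise ValueError(
                f"matrix is {p} genes x {n} samples but got "
                f"{len(self.gene_ids)} gene ids and {len(self.sample_ids)} sample ids"
            )
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            uniq, counts = np.unique(ids, return_counts=True)
            if (counts > 1).any():
                dupes = uniq[counts > 1][:5].tolist()
                raise ValueError(f"duplicate {name} identifiers: {dupes}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing or non-finite values")
        self.classes_, self.y_ = np.unique(self.labels, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")

    # -- basic shape -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.classes_)

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"unknown gene {gene!r}")
        return int(idx[0])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        """Dataset restricted to ``genes``, in the given order."""
        rows = [self.gene_index(g) for g in genes]
        return ExpressionDataset(
            gene_ids=self.gene_ids[rows],
            sample_ids=self.sample_ids,
            values=self.values[rows],
            labels=self.labels,
        )

    def subset_samples(self, index: Sequence[int]) -> "ExpressionDataset":
        index = np.asarray(index, dtype=int)
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            sample_ids=self.sample_ids[index],
            values=self.values[:, index],
            labels=self.labels[index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    # sklearn orientation: samples as rows
    @property
    def X(self) -> np.ndarray:
        """Expression values as a samples x genes array (sklearn orientation)."""
        return self.values.T

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.labels, other.labels)
        )


def _read_table(path: str, delimiter: str | None) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if delimiter is None:
        # auto-detect among tab and comma from the header line
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=delimiter, index_col=0)


def read_labels(path: str, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column (sample_id, class) file into a mapping.

    A header row is tolerated: if the file has one, pandas' column names
    are discarded either way since only the two columns' contents matter.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"labels file must have two columns, got {df.shape[1]}")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return mapping


def load_dataset(
    matrix_path: str,
    labels_path: str,
    orientation: str = "genes-by-samples",
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Load an expression matrix and its labels into an :class:`ExpressionDataset`.

    Parameters
    ----------
    matrix_path : str
        Delimited text matrix with an identifier header row and one
        identifier column.
    labels_path : str
        Two-column (sample_id, class) delimited file.  Every sample in
        the matrix must be labeled; extra labels are ignored.
    orientation : {"genes-by-samples", "samples-by-genes"}
        Layout of the matrix file.  Internally everything is normalised
        to genes x samples, so both orientations of the same data load
        to identical datasets.
    delimiter : str, optional
        Field delimiter; auto-detected among tab and comma when omitted.
    """
    if orientation not in ("genes-by-samples", "samples-by-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(matrix_path, delimiter)
    if orientation == "samples-by-genes":
        df = df.T
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cell in {matrix_path}: {exc}") from exc
    labels_map = read_labels(labels_path, delimiter)
    sample_ids = [str(s) for s in df.columns]
    missing = [s for s in sample_ids if s not in labels_map]
    # a labels file with a header contributes one bogus entry; it only
    # matters if it shadows a real sample id, which it cannot
    if missing:
        raise ValueError(f"unlabeled sample(s): {missing[:5]}")
    labels = [labels_map[s] for s in sample_ids]
    return ExpressionDataset(
        gene_ids=[str(g) for g in df.index],
        sample_ids=sample_ids,
        values=values,
        labels=labels,
    )


def write_dataset(
    dataset: ExpressionDataset, matrix_path: str, labels_path: str, delimiter: str = "\t"
) -> None:
    """Write the matrix (genes x samples) and labels file back to text."""
    dataset.to_frame().to_csv(matrix_path, sep=delimiter)
    pd.DataFrame({"sample_id": dataset.sample_ids, "class": dataset.labels}).to_csv(
        labels_path, sep=delimiter, header=False, index=False
    )


# -- ranked lists, traces, predictions ----------------------------------


def write_ranked_list(ranked, path: str, delimiter: str = "\t") -> None:
    """Write a :class:`~irgdc.ranking.RankedGeneList` as delimited text.

    Columns: rank, gene_id, integrated score S_j, single-gene chi-square.
    Scores are written with full float precision (repr round-trip), so
    reading the file back reproduces them bit-exactly.
    """
    frame = ranked.to_frame()
    if len(frame) == 0:
        raise ValueError("refusing to write an empty ranked list")
    with open(path, "w") as fh:
        fh.write(f"# tie_rule: {ranked.tie_rule}\n")
        fh.write(delimiter.join(["rank", "gene_id", "score", "chi2_single"]) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(
                delimiter.join(
                    [str(row.rank), row.gene_id, repr(float(row.score)), repr(float(row.chi2_single))]
                )
                + "\n"
            )


def read_ranked_list(path: str, delimiter: str = "\t"):
    from .ranking import RankedGeneList

    tie_rule = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            tie_rule = first.lstrip("#").strip().removeprefix("tie_rule:").strip()
            skip = 1
        else:
            skip = 0
    df = pd.read_csv(path, sep=delimiter, skiprows=skip)
    return RankedGeneList(
        gene_ids=df["gene_id"].astype(str).to_numpy(),
        scores=df["score"].to_numpy(dtype=float),
        chi2_single=df["chi2_single"].to_numpy(dtype=float),
        tie_rule=tie_rule or RankedGeneList.DEFAULT_TIE_RULE,
    )


def write_selection_trace(trace, path: str, delimiter: str = "\t") -> None:
    """Write a :class:`~irgdc.selection.SelectionTrace` as delimited text."""
    trace.to_frame().to_csv(path, sep=delimiter, index=False)


def write_predictions(results, path: str, true_labels=None, delimiter: str = "\t") -> None:
    """Write per-sample predictions with per-class chi-square columns.

    ``results`` is a list of (sample_id, ClassScores) pairs.
    """
    rows = []
    for i, (sample_id, scores) in enumerate(results):
        row = {"sample_id": sample_id}
        if true_labels is not None:
            row["true_class"] = true_labels[i]
        row["predicted_class"] = scores.predicted
        for cls, val in scores.per_class.items():
            row[f"chi2_{cls}"] = val
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
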