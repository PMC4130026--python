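"""Contingency tables and chi-square statistics for single and pairwise genes.

Two kinds of m x 2 class-conditional frequency tables drive the whole
method:

* **mean-split table** of a single gene: row k counts samples of class
  C_k whose expression is above (column 1) or below (column 2) the
  gene's mean over all samples in the dataset;
* **pairwise ordering table** of a gene pair (G_j, G_l): row k counts
  samples of class C_k in which x_ij > x_il versus x_ij < x_il, a
  within-sample relative-expression comparison.

Exact ties contribute 0.5 to each column of their class row, so counts
may be fractional while every table's grand total stays equal to the
number of samples.  The chi-square statistic of a table is computed in
the products-of-marginals form

    chi2 = N * (sum_kq f_kq^2 / (n_k * T_q) - 1)

which is algebraically the Pearson statistic sum (O - E)^2 / E with
E_kq = n_k * T_q / N, without continuity correction.  Cells whose row or
column total is zero are necessarily zero and contribute nothing
(0/0 := 0), matching the limit of the Pearson form.  The statistic is
used purely as a score; no p-values or degrees-of-freedom corrections
appear anywhere in the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dataset import ExpressionDataset

__all__ = [
    "ContingencyTable",
    "single_gene_table",
    "pairwise_table",
    "chi_square",
    "all_single_chi_squares",
    "all_pairwise_chi_squares",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An m x 2 table of (possibly fractional) class-conditional counts."""

    counts: np.ndarray  # (m, 2), non-negative reals
    row_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("counts must be an m x 2 matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())


def chi2_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorised chi-square over a stack of tables.

    ``counts`` has shape (..., m, 2); returns shape (...,).  Cells whose
    row or column total is zero contribute zero to the sum.
    """
    counts = np.asarray(counts, dtype=np.float64)
    row = counts.sum(axis=-1, keepdims=True)
    col = counts.sum(axis=-2, keepdims=True)
    grand = counts.sum(axis=(-1, -2))
    denom = row * col
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(denom > 0, counts * counts / denom, 0.0)
    # mathematically >= 0; clamp away negative rounding residue so that
    # independence gives exactly 0 (and zero weights stay exactly zero)
    return np.maximum(grand * (terms.sum(axis=(-1, -2)) - 1.0), 0.0)


def chi_square(table: ContingencyTable | np.ndarray) -> float:
    """Chi-square statistic of one m x 2 table (no continuity correction)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, float)
    if counts.sum() <= 0:
        raise ValueError("empty contingency table")
    return float(chi2_from_counts(counts))


# -- count builders (array level) ---------------------------------------


def _one_hot(y: np.ndarray, m: int) -> np.ndarray:
    yh = np.zeros((len(y), m))
    yh[np.arange(len(y)), y] = 1.0
    return yh


def _split_counts(gt: np.ndarray, lt: np.ndarray, tie: np.ndarray, yh: np.ndarray) -> np.ndarray:
    """Assemble (..., m, 2) counts from boolean comparison masks over samples.

    ``gt``/``lt``/``tie`` have shape (..., n); ``yh`` is the (n, m)
    one-hot class indicator.  Ties add 0.5 to each column of their row.
    """
    half_tie = 0.5 * (tie @ yh)
    c1 = gt.astype(np.float64) @ yh + half_tie
    c2 = lt.astype(np.float64) @ yh + half_tie
    return np.stack([c1, c2], axis=-1)


def mean_split_counts(values: np.ndarray, y: np.ndarray, m: int, tie_tol: float = 0.0) -> np.ndarray:
    """Mean-split tables for a (p, n) value matrix; returns (p, m, 2)."""
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    mu = values.mean(axis=1, keepdims=True)
    d = values - mu
    gt, lt, tie = _compare(d, tie_tol)
    return _split_counts(gt, lt, tie, _one_hot(np.asarray(y), m))


def _compare(d: np.ndarray, tie_tol: float):
    if tie_tol > 0:
        tie = np.abs(d) <= tie_tol
        gt = (d > 0) & ~tie
        lt = (d < 0) & ~tie
    else:
        gt = d > 0
        lt = d < 0
        tie = d == 0
    return gt, lt, tie


def ordering_counts(diff: np.ndarray, y: np.ndarray, m: int, tie_tol: float = 0.0) -> np.ndarray:
    """Pairwise ordering tables from within-sample differences.

    ``diff`` has shape (..., n) holding x_ij - x_il per sample for each
    pair; returns (..., m, 2) counts.
    """
    gt, lt, tie = _compare(np.asarray(diff, dtype=np.float64), tie_tol)
    return _split_counts(gt, lt, tie, _one_hot(np.asarray(y), m))


def pairwise_chi2_matrix(values: np.ndarray, y: np.ndarray, m: int, tie_tol: float = 0.0) -> np.ndarray:
    """Full symmetric (p, p) matrix of pairwise ordering chi-squares.

    Computed row-block by row-block to keep memory at O(p * n); the
    diagonal is zero (self-pairs have no table).
    """
    values = np.asarray(values, dtype=np.float64)
    p = values.shape[0]
    yh = _one_hot(np.asarray(y), m)
    out = np.zeros((p, p))
    for j in range(p - 1):
        diff = values[j][None, :] - values[j + 1 :]  # (p-j-1, n)
        counts = ordering_counts(diff, y, m, tie_tol)
        chi = chi2_from_counts(counts)
        out[j, j + 1 :] = chi
        out[j + 1 :, j] = chi
    return out


# -- dataset-level operations -------------------------------------------


def single_gene_table(
    dataset: ExpressionDataset, gene: str, tie_tol: float = 0.0
) -> ContingencyTable:
    """Mean-split m x 2 table for one gene.

    The split point is the gene's mean over *all* samples of the dataset
    the table is built from (the training set during selection); samples
    exactly at the mean contribute 0.5 to each column of their class row.
    """
    row = dataset.values[dataset.gene_index(gene)]
    counts = mean_split_counts(row[None, :], dataset.y_, dataset.n_classes, tie_tol)[0]
    return ContingencyTable(counts, row_labels=tuple(dataset.classes_))


def pairwise_table(
    dataset: ExpressionDataset, gene_j: str, gene_l: str, tie_tol: float = 0.0
) -> ContingencyTable:
    """Pairwise ordering m x 2 table for genes (G_j, G_l)."""
    if gene_j == gene_l:
        raise ValueError("pairwise table requires two distinct genes")
    diff = dataset.values[dataset.gene_index(gene_j)] - dataset.values[dataset.gene_index(gene_l)]
    counts = ordering_counts(diff[None, :], dataset.y_, dataset.n_classes, tie_tol)[0]
    return ContingencyTable(counts, row_labels=tuple(dataset.classes_))


def all_single_chi_squares(dataset: ExpressionDataset, tie_tol: float = 0.0) -> dict[str, float]:
    """Single-gene chi-square for every gene, as gene_id -> value."""
    counts = mean_split_counts(dataset.values, dataset.y_, dataset.n_classes, tie_tol)
    chi = chi2_from_counts(counts)
    return dict(zip(dataset.gene_ids.tolist(), chi.tolist()))


def all_pairwise_chi_squares(
    dataset: ExpressionDataset,
    genes: Sequence[str] | None = None,
    tie_tol: float = 0.0,
) -> dict[tuple[str, str], float]:
    """Pairwise ordering chi-square for every unordered gene pair.

    Returned mapping contains both orderings of each pair; the statistic
    is symmetric because swapping the genes swaps the table's columns.
    """
    sub = dataset if genes is None else dataset.subset_genes(genes)
    if sub.n_genes < 2:
        raise ValueError("need at least two genes for pairwise statistics")
    mat = pairwise_chi2_matrix(sub.values, sub.y_, sub.n_classes, tie_tol)
    ids = sub.gene_ids.tolist()
    out: dict[tuple[str, str], float] = {}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            val = float(mat[a, b])
            out[(ids[a], ids[b])] = val
            out[(ids[b], ids[a])] = val
    return out
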