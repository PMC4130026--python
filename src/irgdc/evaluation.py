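"""End-to-end pipeline and reporting.

``run_pipeline`` composes the full method — rank all genes on the
training set, forward-select informative genes by LOOCV, classify the
independent test set with the direct classifier — while enforcing
strict train/test separation: the test set never participates in
ranking or selection.  Reports carry the overall accuracy (correctly
classified / total) plus a per-class breakdown for diagnosing class
imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import ClassScores, classify_batch
from .dataset import ExpressionDataset
from .ranking import RankedGeneList, rank_genes
from .selection import SelectionTrace, select_informative_genes

__all__ = ["EvaluationReport", "run_pipeline", "overlap_report"]


@dataclass
class EvaluationReport:
    """Result of one train/test run of the full pipeline."""

    train_loocv: float
    train_mean_margin: float
    test_accuracy: float
    n_selected: int
    selected_genes: list[str]
    per_class_accuracy: dict[str, float]
    ranked: RankedGeneList
    trace: SelectionTrace
    test_results: list[tuple[str, ClassScores]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("train_loocv", self.train_loocv),
            ("train_mean_margin", self.train_mean_margin),
            ("test_accuracy", self.test_accuracy),
            ("n_selected", self.n_selected),
            ("selected_genes", ",".join(self.selected_genes)),
        ]
        rows += [(f"accuracy[{c}]", v) for c, v in self.per_class_accuracy.items()]
        return pd.DataFrame(rows, columns=["metric", "value"])


def run_pipeline(
    train: ExpressionDataset,
    test: ExpressionDataset,
    cap_fraction: float = 0.02,
    pair_prefilter: int | None = None,
    tie_tol: float = 0.0,
) -> EvaluationReport:
    """Rank on train, select on train, predict the independent test set."""
    if set(test.gene_ids) < set(train.gene_ids):
        missing = sorted(set(train.gene_ids) - set(test.gene_ids))
        raise ValueError(f"test set lacks training genes: {missing[:5]}")
    ranked = rank_genes(train, tie_tol=tie_tol, pair_prefilter=pair_prefilter)
    trace = select_informative_genes(train, ranked, cap_fraction, tie_tol)
    genes = trace.selected
    results, accuracy = classify_batch(train, genes, test, tie_tol)

    preds = np.array([scores.predicted for scores in results])
    per_class: dict[str, float] = {}
    for cls in np.unique(test.labels):
        mask = test.labels == cls
        per_class[str(cls)] = float(np.mean(preds[mask] == cls))

    return EvaluationReport(
        train_loocv=trace.final_loocv,
        train_mean_margin=trace.final_mean_margin,
        test_accuracy=accuracy,
        n_selected=len(genes),
        selected_genes=list(genes),
        per_class_accuracy=per_class,
        ranked=ranked,
        trace=trace,
        test_results=list(zip(test.sample_ids.tolist(), results)),
    )


def overlap_report(lists: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Pairwise overlap counts between named gene lists.

    Returns a symmetric DataFrame whose diagonal holds the (distinct)
    list sizes and whose off-diagonal entries count shared genes.
    """
    if len(lists) < 2:
        raise ValueError("overlap report needs at least two gene lists")
    names = list(lists)
    sets = {name: set(lists[name]) for name in names}
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            mat.loc[a, b] = len(sets[a] & sets[b])
    return mat
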