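"""Sequential forward selection of informative genes with redundancy removal.

Starting from the top two genes of the ordered list Theta, candidates
are introduced one at a time in Theta order, up to a cap of the top 2%
of the list (minimum two genes).  Each candidate is evaluated by
leave-one-out cross-validation (LOOCV) of the direct classifier on the
training set: the candidate is accepted iff the LOOCV accuracy strictly
increases, or stays equal while the mean margin h-bar strictly
increases; otherwise it is deemed redundant and permanently discarded.
The procedure is purely forward — the initial pair is never revisited
and there is no backward pass — and entirely deterministic.

LOOCV here never rebuilds tables from scratch: the full-training pair
tables are cached once per gene subset and each fold applies two unit
updates (remove the held-out sample's row contribution, re-add it under
each hypothesized class).  Because all counts are half-integers this is
bit-exact against naive per-fold recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .classifier import _margins_from_scores, _pair_add_vectors, _hypothesis_scores
from .dataset import ExpressionDataset
from .ranking import RankedGeneList, compute_scores, rank_genes, theta_order
from .stats import ordering_counts

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "loocv_evaluate",
    "select_informative_genes",
    "InformativeGeneSelector",
]


@dataclass(frozen=True)
class SelectionStep:
    """One examined candidate: its rank in Theta, the tentative
    (LOOCV, h-bar) with it added, and the accept/reject decision."""

    gene: str
    rank_in_theta: int  # 1-based rank
    loocv_accuracy: float
    mean_margin: float
    decision: str  # "accept" | "reject"


@dataclass
class SelectionTrace:
    """Full record of a forward-selection run."""

    initial: tuple[str, str]
    initial_loocv: float
    initial_mean_margin: float
    steps: list[SelectionStep]
    selected: list[str]
    cap: int

    @property
    def final_loocv(self) -> float:
        accepted = [s for s in self.steps if s.decision == "accept"]
        return accepted[-1].loocv_accuracy if accepted else self.initial_loocv

    @property
    def final_mean_margin(self) -> float:
        accepted = [s for s in self.steps if s.decision == "accept"]
        return accepted[-1].mean_margin if accepted else self.initial_mean_margin

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "candidate_gene": "+".join(self.initial),
                "rank_in_theta": "1+2",
                "loocv_accuracy": self.initial_loocv,
                "mean_margin": self.initial_mean_margin,
                "decision": "initial",
            }
        ]
        for s in self.steps:
            rows.append(
                {
                    "candidate_gene": s.gene,
                    "rank_in_theta": str(s.rank_in_theta),
                    "loocv_accuracy": s.loocv_accuracy,
                    "mean_margin": s.mean_margin,
                    "decision": s.decision,
                }
            )
        return pd.DataFrame(rows)


# -- LOOCV core ---------------------------------------------------------


def loocv_class_scores(X: np.ndarray, y: np.ndarray, m: int, tie_tol: float = 0.0) -> np.ndarray:
    """Per-sample, per-hypothesis chi-square scores under LOOCV.

    ``X`` is samples x genes (r >= 2 columns), ``y`` integer class codes.
    For each sample i the reference tables are the cached full-data
    tables minus sample i's contribution; sample i is then re-added
    under each hypothesized class.  Returns (n, m).
    """
    n, r = X.shape
    if r < 2:
        raise ValueError("LOOCV evaluation needs at least 2 genes")
    iu, ju = np.triu_indices(r, k=1)
    diffs = X[:, iu] - X[:, ju]  # (n, P)
    add_gt, add_lt = _pair_add_vectors(diffs, tie_tol)
    base = ordering_counts(diffs.T, y, m, tie_tol)  # (P, m, 2)
    scores = np.empty((n, m))
    for i in range(n):
        loo = base.copy()
        loo[:, y[i], 0] -= add_gt[i]
        loo[:, y[i], 1] -= add_lt[i]
        scores[i] = _hypothesis_scores(loo, add_gt[i], add_lt[i])
    return scores


def _loocv_metrics(X: np.ndarray, y: np.ndarray, m: int, tie_tol: float) -> tuple[float, float]:
    scores = loocv_class_scores(X, y, m, tie_tol)
    correct = np.argmax(scores, axis=1) == y
    margins = _margins_from_scores(scores, y, "zero")
    return float(correct.mean()), float(margins.mean())


def loocv_evaluate(
    train: ExpressionDataset, genes: Sequence[str], tie_tol: float = 0.0
) -> tuple[float, float]:
    """LOOCV accuracy and mean margin h-bar of a gene subset.

    Each training sample is held out, classified by the direct
    classifier on the remaining n - 1 samples, and its margin h
    (relative to its true class) recorded; a held-out sample whose
    true-class score is zero contributes h = 0.
    """
    sub = train.subset_genes(list(genes))
    return _loocv_metrics(sub.X, sub.y_, sub.n_classes, tie_tol)


# -- forward selection --------------------------------------------------


def _forward_select(
    X: np.ndarray,
    y: np.ndarray,
    m: int,
    theta: np.ndarray,
    ids: np.ndarray,
    cap_fraction: float,
    tie_tol: float,
) -> tuple[SelectionTrace, np.ndarray]:
    """Core loop over column indices; ``theta`` orders columns of X."""
    p = len(theta)
    if p < 2:
        raise ValueError("selection needs at least two ranked genes")
    cap = max(2, int(round(cap_fraction * p)))
    selected = [int(theta[0]), int(theta[1])]
    acc, hbar = _loocv_metrics(X[:, selected], y, m, tie_tol)
    trace = SelectionTrace(
        initial=(str(ids[selected[0]]), str(ids[selected[1]])),
        initial_loocv=acc,
        initial_mean_margin=hbar,
        steps=[],
        selected=[],
        cap=cap,
    )
    for rank in range(2, cap):
        cand = int(theta[rank])
        cand_acc, cand_hbar = _loocv_metrics(X[:, selected + [cand]], y, m, tie_tol)
        accept = cand_acc > acc or (cand_acc == acc and cand_hbar > hbar)
        trace.steps.append(
            SelectionStep(
                gene=str(ids[cand]),
                rank_in_theta=rank + 1,
                loocv_accuracy=cand_acc,
                mean_margin=cand_hbar,
                decision="accept" if accept else "reject",
            )
        )
        if accept:
            selected.append(cand)
            acc, hbar = cand_acc, cand_hbar
    trace.selected = [str(ids[i]) for i in selected]
    return trace, np.array(selected, dtype=int)


def select_informative_genes(
    train: ExpressionDataset,
    ranked: RankedGeneList,
    cap_fraction: float = 0.02,
    tie_tol: float = 0.0,
) -> SelectionTrace:
    """Run the forward procedure over a precomputed ordered list Theta.

    ``cap_fraction`` bounds the candidates examined to the head of
    Theta: cap = max(2, round(cap_fraction * p)), counting the initial
    two genes.
    """
    if len(ranked) < 2:
        raise ValueError("ranked list must contain at least two genes")
    sub = train.subset_genes(ranked.gene_ids.tolist())
    theta = np.arange(sub.n_genes)  # columns already in Theta order
    trace, _ = _forward_select(
        sub.X, sub.y_, sub.n_classes, theta, sub.gene_ids, cap_fraction, tie_tol
    )
    return trace


class InformativeGeneSelector(SelectorMixin, BaseEstimator):
    """Feature selector: integrated chi-square ranking + forward LOOCV search.

    scikit-learn transformer over samples x genes matrices.  ``fit``
    ranks all genes by the integrated weighted score S_j, then runs the
    sequential forward procedure driven by LOOCV accuracy of the direct
    classifier; ``transform`` keeps the selected columns.

    Parameters
    ----------
    cap_fraction : float, default 0.02
        Fraction of the ranked list examined as candidates (minimum 2
        genes, including the initial pair).
    pair_prefilter : int or None, default None
        Restrict pairwise chi-square evaluation during ranking to the
        top-K genes by single-gene chi-square (None = all pairs).
    tie_tol : float, default 0.0
        Tie tolerance for expression comparisons.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Integrated weighted score S_j per input column.
    chi2_single_ : ndarray of shape (n_features,)
        Single-gene chi-square per input column.
    ranking_ : ndarray of shape (n_features,)
        Column indices in Theta order (best first).
    selected_idx_ : ndarray
        Selected column indices, in acceptance order.
    trace_ : SelectionTrace
        Full per-candidate record.
    """

    def __init__(
        self,
        cap_fraction: float = 0.02,
        pair_prefilter: int | None = None,
        tie_tol: float = 0.0,
    ):
        self.cap_fraction = cap_fraction
        self.pair_prefilter = pair_prefilter
        self.tie_tol = tie_tol

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if X.shape[1] < 2:
            raise ValueError("need at least two genes to rank and select")
        classes, y_codes = np.unique(np.asarray(y), return_inverse=True)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        scores, chi_single = compute_scores(
            X.T, y_codes, len(classes), self.tie_tol, self.pair_prefilter
        )
        self.scores_ = scores
        self.chi2_single_ = chi_single
        idx = np.arange(X.shape[1])
        self.ranking_ = theta_order(scores, chi_single, idx)
        trace, selected = _forward_select(
            X, y_codes, len(classes), self.ranking_, idx.astype(str),
            self.cap_fraction, self.tie_tol,
        )
        self.trace_ = trace
        self.selected_idx_ = selected
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "selected_idx_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        return mask
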