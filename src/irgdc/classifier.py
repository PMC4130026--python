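"""The training-free chi-square direct classifier.

To classify a test sample over r selected genes, each of the m classes
is tried as a hypothesis: the sample is provisionally added to that
class and all r(r-1)/2 pairwise ordering tables are rebuilt over the
n + 1 samples.  The class score chi2_(C_k) is the sum of the r(r-1)/2
chi-square statistics, and the sample is assigned to the class with the
largest score.  Adding the sample to its true class tends to reinforce
the existing class-conditional orderings (raising the statistics), while
a wrong hypothesis dilutes them — no parameters are ever fitted, the
only state is the reference data itself.

Because the tables depend only on within-sample orderings, predictions
are invariant under any strictly increasing transformation applied
per sample — the robustness to monotone batch distortions shared by the
whole relative-expression (top-scoring-pairs) family.

The margin of a sample with known true class C_t is

    h = sum_{k != t} (chi2_(C_t) - chi2_(C_k)) / chi2_(C_t)

which lies in (-inf, m - 1] and is 0 when all class scores coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dataset import ExpressionDataset
from .stats import chi2_from_counts, ordering_counts, _compare

__all__ = [
    "ClassScores",
    "ChiSquareDirectClassifier",
    "classify_sample",
    "margin_h",
    "classify_batch",
]


@dataclass
class ClassScores:
    """Per-class summed pairwise chi-squares for one test sample."""

    per_class: dict[str, float]
    predicted: str
    margin: float | None = None

    def __post_init__(self) -> None:
        if self.predicted not in self.per_class:
            raise ValueError("predicted class missing from per_class scores")


def _pair_add_vectors(diff: np.ndarray, tie_tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (column-1, column-2) increments contributed by one sample."""
    gt, lt, tie = _compare(diff, tie_tol)
    half = 0.5 * tie
    return gt + half, lt + half


def _hypothesis_scores(
    base_counts: np.ndarray, add_gt: np.ndarray, add_lt: np.ndarray
) -> np.ndarray:
    """Summed chi-square per class hypothesis.

    ``base_counts`` (P, m, 2) are the reference tables; the sample's
    increments are added to row k for each hypothesized class k.  The
    returned (m,) vector sums the P per-pair statistics.
    """
    m = base_counts.shape[1]
    stacked = np.repeat(base_counts[None, :, :, :], m, axis=0)  # (m, P, m, 2)
    k = np.arange(m)
    stacked[k, :, k, 0] += add_gt
    stacked[k, :, k, 1] += add_lt
    return chi2_from_counts(stacked).sum(axis=1)


class ChiSquareDirectClassifier(ClassifierMixin, BaseEstimator):
    """Direct classifier over within-sample pairwise expression orderings.

    scikit-learn estimator: ``X`` is samples x genes.  ``fit`` only
    stores the reference data (and caches its pairwise ordering tables,
    a pure function of the data); there are no fitted parameters.

    Parameters
    ----------
    tie_tol : float, default 0.0
        Absolute tolerance below which a within-sample expression
        difference is declared a tie (counted 0.5/0.5).  The default
        treats only exact floating-point equality as a tie.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    X_ : ndarray of shape (n_samples, n_features)
        Reference expression values.
    y_ : ndarray
        Integer class codes of the reference samples.
    """

    def __init__(self, tie_tol: float = 0.0):
        self.tie_tol = tie_tol

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if X.shape[1] < 2:
            raise ValueError("chi-square direct classification needs at least 2 genes")
        self.classes_, self.y_ = np.unique(np.asarray(y), return_inverse=True)
        self.X_ = X
        self.n_features_in_ = X.shape[1]
        iu, ju = np.triu_indices(X.shape[1], k=1)
        self._iu, self._ju = iu, ju
        diffs = X[:, iu] - X[:, ju]  # (n, P)
        self._base_counts_ = ordering_counts(
            diffs.T, self.y_, len(self.classes_), self.tie_tol
        )  # (P, m, 2)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-class summed chi-square scores, shape (n_samples, n_classes).

        Scores are not normalised across classes; only the argmax (and
        the margin h derived from it) is meaningful.
        """
        check_is_fitted(self, "X_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        out = np.empty((X.shape[0], len(self.classes_)))
        for i, row in enumerate(X):
            add_gt, add_lt = _pair_add_vectors(row[self._iu] - row[self._ju], self.tie_tol)
            out[i] = _hypothesis_scores(self._base_counts_, add_gt, add_lt)
        return out

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        # np.argmax takes the first maximum: ties resolve to the fixed
        # sorted class order
        return self.classes_[np.argmax(scores, axis=1)]

    def margins(self, X, y, zero_policy: str = "zero") -> np.ndarray:
        """Margin h of each sample given its true class.

        ``zero_policy`` controls the degenerate case chi2_(C_t) = 0:
        ``"zero"`` records h = 0 with a warning (no evidence either
        way), ``"raise"`` raises.
        """
        scores = self.decision_function(X)
        y = np.asarray(y)
        t = np.searchsorted(self.classes_, y)
        if not np.array_equal(self.classes_[t], y):
            raise ValueError("true labels contain classes unseen in the reference set")
        return _margins_from_scores(scores, t, zero_policy)


def _margins_from_scores(scores: np.ndarray, true_idx: np.ndarray, zero_policy: str) -> np.ndarray:
    st = scores[np.arange(len(scores)), true_idx]
    zero = st <= 0
    if zero.any():
        if zero_policy == "raise":
            raise ValueError("true-class chi-square score is 0; margin h undefined")
        warnings.warn(
            "true-class chi-square score is 0 for some samples; recording h = 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(zero[:, None], 0.0, (st[:, None] - scores) / np.where(st > 0, st, 1.0)[:, None])
    return h.sum(axis=1)  # the k = t term is exactly 0


# -- dataset-level wrappers ---------------------------------------------


def _fitted_on(train: ExpressionDataset, genes: Sequence[str], tie_tol: float):
    sub = train.subset_genes(genes)
    clf = ChiSquareDirectClassifier(tie_tol=tie_tol)
    clf.fit(sub.X, sub.labels)
    return clf, sub


def classify_sample(
    train: ExpressionDataset,
    genes: Sequence[str],
    test_values: Mapping[str, float],
    tie_tol: float = 0.0,
) -> ClassScores:
    """Classify a single sample given as a gene -> value mapping."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    missing = [g for g in genes if g not in test_values]
    if missing:
        raise KeyError(f"test sample lacks values for genes {missing[:5]}")
    clf, _ = _fitted_on(train, genes, tie_tol)
    row = np.array([[float(test_values[g]) for g in genes]])
    scores = clf.decision_function(row)[0]
    pred = clf.classes_[int(np.argmax(scores))]
    return ClassScores(
        per_class=dict(zip(clf.classes_.tolist(), scores.tolist())), predicted=str(pred)
    )


def margin_h(scores: ClassScores, true_class: str, zero_policy: str = "raise") -> float:
    """Margin h from a :class:`ClassScores` and the sample's true class."""
    if true_class not in scores.per_class:
        raise KeyError(f"unknown class {true_class!r}")
    classes = sorted(scores.per_class)
    vec = np.array([[scores.per_class[c] for c in classes]])
    t = np.array([classes.index(true_class)])
    return float(_margins_from_scores(vec, t, zero_policy)[0])


def classify_batch(
    train: ExpressionDataset,
    genes: Sequence[str],
    test: ExpressionDataset,
    tie_tol: float = 0.0,
) -> tuple[list[ClassScores], float]:
    """Classify every test sample independently against the same reference.

    Returns the per-sample :class:`ClassScores` (with margins where the
    test label is a known class) and the overall accuracy.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    clf, _ = _fitted_on(train, genes, tie_tol)
    test_sub = test.subset_genes(genes)  # raises on absent genes
    scores = clf.decision_function(test_sub.X)
    preds = clf.classes_[np.argmax(scores, axis=1)]
    results = []
    known = np.isin(test_sub.labels, clf.classes_)
    for i in range(test_sub.n_samples):
        margin = None
        if known[i]:
            t = np.array([int(np.searchsorted(clf.classes_, test_sub.labels[i]))])
            margin = float(_margins_from_scores(scores[i : i + 1], t, "zero")[0])
        results.append(
            ClassScores(
                per_class=dict(zip(clf.classes_.tolist(), scores[i].tolist())),
                predicted=str(preds[i]),
                margin=margin,
            )
        )
    accuracy = float(np.mean(preds == test_sub.labels))
    return results, accuracy
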