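"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as a direct, unoptimised transcription of the
definitions — per-sample Python loops and from-scratch table rebuilding —
deliberately sharing no code path with the package's vectorised or
incrementally-updated routines.
"""

from __future__ import annotations

import numpy as np


def pearson_chi2(counts) -> float:
    """Textbook Pearson sum((O - E)^2 / E) with E = row * col / N.

    Cells with E = 0 are skipped (their O is necessarily 0).
    """
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    E = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / N
    total = 0.0
    for k in range(counts.shape[0]):
        for q in range(counts.shape[1]):
            if E[k, q] > 0:
                total += (counts[k, q] - E[k, q]) ** 2 / E[k, q]
    return total


def mean_split_table(values, y, m) -> np.ndarray:
    """Single-gene table by direct enumeration of the definition."""
    values = np.asarray(values, dtype=float)
    mu = values.mean()
    counts = np.zeros((m, 2))
    for x, k in zip(values, y):
        if x > mu:
            counts[k, 0] += 1
        elif x < mu:
            counts[k, 1] += 1
        else:
            counts[k, 0] += 0.5
            counts[k, 1] += 0.5
    return counts


def ordering_table(vj, vl, y, m) -> np.ndarray:
    """Pairwise ordering table by direct enumeration."""
    counts = np.zeros((m, 2))
    for a, b, k in zip(vj, vl, y):
        if a > b:
            counts[k, 0] += 1
        elif a < b:
            counts[k, 1] += 1
        else:
            counts[k, 0] += 0.5
            counts[k, 1] += 0.5
    return counts


def integrated_score_naive(chi_single: dict, chi_pair: dict, gene) -> float:
    """Term-by-term transcription of the integrated weighted score."""
    cj = chi_single[gene]
    s = cj
    for other, cl in chi_single.items():
        if other == gene:
            continue
        pair = chi_pair.get((gene, other), chi_pair.get((other, gene)))
        if cj + cl > 0:
            s += cj / (cj + cl) * pair
    return s


def class_scores_from_scratch(chi2_fn, X_train, y_train, m, test_row) -> np.ndarray:
    """Per-hypothesis scores by rebuilding every (n+1)-sample table.

    ``X_train`` is samples x genes; the test sample is appended with
    each hypothesized class label in turn and all r(r-1)/2 ordering
    tables are rebuilt from scratch.  ``chi2_fn`` maps an m x 2 count
    matrix to its statistic.
    """
    r = X_train.shape[1]
    scores = np.zeros(m)
    for k in range(m):
        X_aug = np.vstack([X_train, test_row])
        y_aug = np.concatenate([y_train, [k]])
        per_pair = [
            chi2_fn(ordering_table(X_aug[:, j], X_aug[:, l], y_aug, m))
            for j in range(r)
            for l in range(j + 1, r)
        ]
        # np.sum, so the reduction order matches any vectorised caller;
        # the independence of this oracle lies in the table rebuilding
        scores[k] = np.sum(per_pair)
    return scores


def margin_naive(scores, t) -> float:
    """Explicit-loop transcription of the margin h."""
    st = scores[t]
    if st <= 0:
        return 0.0
    return sum((st - scores[k]) / st for k in range(len(scores)) if k != t)


def loocv_from_scratch(chi2_fn, X, y, m) -> tuple[float, float]:
    """Naive LOOCV: rebuild the reference set per fold, no caching."""
    n = X.shape[0]
    correct = 0
    margins = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        scores = class_scores_from_scratch(chi2_fn, X[keep], y[keep], m, X[i])
        pred = int(np.argmax(scores))
        correct += pred == y[i]
        margins.append(margin_naive(scores, y[i]))
    return correct / n, float(np.mean(margins))


def random_instance(rng, n, r, m, integer_values=False):
    """A random labeled samples x genes matrix with every class present."""
    if integer_values:
        X = rng.integers(0, 6, size=(n, r)).astype(float)
    else:
        X = rng.normal(size=(n, r))
    y = np.concatenate([np.arange(m), rng.integers(0, m, size=n - m)])
    rng.shuffle(y)
    return X, y
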