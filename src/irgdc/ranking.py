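"""Integrated weighted gene scores and the ordered gene list Theta.

A gene's importance combines its main effect with its pairwise
interactions: the integrated weighted score of gene G_j is

    S_j = chi2_j + sum_{l != j} [ chi2_j / (chi2_j + chi2_l) ] * chi2_{j,l}

where chi2_j is the single-gene (mean-split) statistic and chi2_{j,l}
the pairwise ordering statistic.  Each pair's statistic is shared
between its two ends in proportion to their single-gene strengths, so
the two weights of a pair sum to one and the total pairwise mass is
conserved across the ranking.  A gene with chi2_j = 0 receives weight 0
everywhere and S_j = 0; when both ends have zero single-gene statistic
the 0/0 weight is defined as 0 and the pair contributes to neither.

Genes sorted by descending S_j form the ordered list Theta consumed by
the forward-selection procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .stats import mean_split_counts, chi2_from_counts, pairwise_chi2_matrix

__all__ = ["RankedGeneList", "integrated_score", "integrated_scores", "rank_genes"]


@dataclass
class RankedGeneList:
    """Genes ordered by descending integrated weighted score S_j."""

    DEFAULT_TIE_RULE = "descending S_j, then descending single chi2, then gene_id"

    gene_ids: np.ndarray
    scores: np.ndarray
    chi2_single: np.ndarray
    tie_rule: str = DEFAULT_TIE_RULE

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.chi2_single = np.asarray(self.chi2_single, dtype=np.float64)
        if not (len(self.gene_ids) == len(self.scores) == len(self.chi2_single)):
            raise ValueError("mismatched ranked-list column lengths")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("ranked-list scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "gene_id": self.gene_ids,
                "score": self.scores,
                "chi2_single": self.chi2_single,
            }
        )


def integrated_score(
    chi_single: Mapping[str, float],
    chi_pair: Mapping[tuple[str, str], float],
    gene: str,
) -> float:
    """S_j for one gene from precomputed single and pairwise statistics.

    ``chi_pair`` must cover every pair (gene, l) for l != gene, in either
    key order.
    """
    if gene not in chi_single:
        raise KeyError(f"unknown gene {gene!r}")
    cj = chi_single[gene]
    total = cj
    for other, cl in chi_single.items():
        if other == gene:
            continue
        if (gene, other) in chi_pair:
            pair = chi_pair[(gene, other)]
        elif (other, gene) in chi_pair:
            pair = chi_pair[(other, gene)]
        else:
            raise KeyError(f"missing pairwise value for ({gene}, {other})")
        denom = cj + cl
        if denom > 0:
            total += cj / denom * pair
    return float(total)


def integrated_scores(
    chi_single: np.ndarray, chi_pair_matrix: np.ndarray
) -> np.ndarray:
    """Vectorised S_j for all genes.

    ``chi_single`` is (p,); ``chi_pair_matrix`` the symmetric (p, p)
    pairwise matrix with zero diagonal.
    """
    c = np.asarray(chi_single, dtype=np.float64)
    denom = c[:, None] + c[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, c[:, None] / denom, 0.0)
    np.fill_diagonal(w, 0.0)
    return c + (w * chi_pair_matrix).sum(axis=1)


def compute_scores(
    values: np.ndarray,
    y: np.ndarray,
    m: int,
    tie_tol: float = 0.0,
    pair_prefilter: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrated scores S_j and single-gene chi-squares for a (p, n) matrix.

    With ``pair_prefilter`` set, pairwise statistics are evaluated only
    among the top ``pair_prefilter`` genes by single-gene chi-square and
    all other genes score S_j = chi2_j; the default evaluates every pair.
    """
    values = np.asarray(values, dtype=np.float64)
    p = values.shape[0]
    counts = mean_split_counts(values, y, m, tie_tol)
    chi_single = chi2_from_counts(counts)
    if pair_prefilter is not None and pair_prefilter < p:
        keep = np.argsort(-chi_single, kind="stable")[:pair_prefilter]
        sub_mat = pairwise_chi2_matrix(values[keep], y, m, tie_tol)
        scores = chi_single.copy()
        scores[keep] = integrated_scores(chi_single[keep], sub_mat)
    else:
        pair_mat = pairwise_chi2_matrix(values, y, m, tie_tol)
        scores = integrated_scores(chi_single, pair_mat)
    return scores, chi_single


def theta_order(scores: np.ndarray, chi_single: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Indices sorting genes into the ordered list Theta.

    Descending S_j; ties broken by larger single-gene chi-square, then
    by ``ids`` (gene identifiers, or feature indices), so the ranking is
    fully deterministic.
    """
    # lexsort: last key is primary
    return np.lexsort((ids, -chi_single, -scores))


def rank_genes(
    dataset: ExpressionDataset,
    tie_tol: float = 0.0,
    pair_prefilter: int | None = None,
) -> RankedGeneList:
    """Compute all statistics and return the ordered list Theta.

    See :func:`compute_scores` for the ``pair_prefilter`` trade-off and
    :func:`theta_order` for the deterministic tie-break chain.
    """
    if dataset.n_genes < 2:
        raise ValueError("ranking needs at least two genes")
    scores, chi_single = compute_scores(
        dataset.values, dataset.y_, dataset.n_classes, tie_tol, pair_prefilter
    )
    tie_rule = RankedGeneList.DEFAULT_TIE_RULE
    if pair_prefilter is not None and pair_prefilter < dataset.n_genes:
        tie_rule += f"; pair_prefilter={pair_prefilter}"
    order = theta_order(scores, chi_single, dataset.gene_ids)
    return RankedGeneList(
        gene_ids=dataset.gene_ids[order],
        scores=scores[order],
        chi2_single=chi_single[order],
        tie_rule=tie_rule,
    )
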