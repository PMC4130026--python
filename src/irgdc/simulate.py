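"""Synthetic expression datasets with planted, known ground truth.

The generator emulates the two signal structures the method is built to
detect:

* **single-gene shifts** — genes whose class-conditional means differ
  by a stated effect size (in units of the gene's noise SD), the signal
  a mean-split table sees;
* **planted pairs** — gene pairs whose within-sample ordering is
  class-dependent (gene_a > gene_b in the first class, reversed in the
  others), with an independent per-sample flip probability, the signal
  a pairwise ordering table sees.

Everything else is pure class-independent noise.  Each planted pair is
built from a shared per-sample latent level plus a signed class offset
split between the two genes:

    gene_a = L + s_c * d/2 + eps_a,   gene_b = L - s_c * d/2 + eps_b

with L ~ N(0, 1) the shared level, eps ~ N(0, 1) gene-specific noise,
s_c = +1 in the first class and -1 otherwise, and the offset
d = sqrt(2) * Phi^-1(1 - flip_prob) chosen so the per-sample
probability of the "wrong" ordering is exactly flip_prob.  At
flip_prob = 0 (infinite offset) the ordering is enforced by reflecting
the gene-specific noise difference instead.  Datasets are fully
reproducible from the seed, and the train/test split is stratified by
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .dataset import ExpressionDataset

__all__ = ["SyntheticConfig", "generate"]


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic study.

    Defaults describe the package's reference recovery setting: two
    balanced classes of 60 samples each (split 50/50 into train and
    test, i.e. 30 + 30 training samples), 200 noise genes, two
    single-shift marker genes at |effect| = 2 noise SDs — one up- and
    one down-regulated, the typical two-marker configuration — and one
    planted pair with a 5% per-sample order-flip probability.

    Attributes
    ----------
    n_per_class : sequence of int
        Total samples per class (train + test together).
    n_noise_genes : int
        Pure-noise genes, class-independent.
    planted_single : sequence of (effect_size, noise_sd)
        One planted shift gene per entry; class k's mean is
        ``effect_size * noise_sd * k`` plus Gaussian noise of SD
        ``noise_sd`` (a negative effect plants a down-regulated gene).
    planted_pairs : sequence of float
        One planted gene pair per entry; the value is the per-sample
        flip probability in [0, 0.5).
    test_fraction : float
        Stratified fraction of each class held out as the test set.
    noise_model : {"normal", "lognormal"}
        Baseline noise family; "lognormal" exponentiates every value,
        mimicking the positivity of expression data without changing
        any within-sample ordering.
    """

    n_per_class: Sequence[int] = (60, 60)
    n_noise_genes: int = 200
    planted_single: Sequence[tuple[float, float]] = ((2.0, 1.0), (-2.0, 1.0))
    planted_pairs: Sequence[float] = (0.05,)
    seed: int = 0
    test_fraction: float = 0.5
    noise_model: str = "normal"

    def validate(self) -> None:
        if len(self.n_per_class) < 2:
            raise ValueError("need at least two classes")
        if any(n <= 0 for n in self.n_per_class):
            raise ValueError("all class sizes must be positive")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be non-negative")
        for f in self.planted_pairs:
            if not (0.0 <= f < 0.5):
                raise ValueError(f"flip probability must lie in [0, 0.5), got {f}")
        for e, sd in self.planted_single:
            if not np.isfinite(e) or sd <= 0:
                raise ValueError("planted single effects must be finite with sd > 0")
        if not (0.0 <= self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in [0, 1)")
        if self.noise_model not in ("normal", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.test_fraction > 0 and any(n < 2 for n in self.n_per_class):
            raise ValueError(
                "cannot split a class with fewer than 2 samples into train and test"
            )


def generate(
    config: SyntheticConfig | None = None, **overrides
) -> tuple[ExpressionDataset, ExpressionDataset | None, list[str]]:
    """Generate (train, test, truth) from a :class:`SyntheticConfig`.

    ``truth`` lists the planted (informative) gene identifiers.  With
    ``test_fraction = 0`` the test dataset is None.  Keyword overrides
    are applied on top of ``config`` (or the defaults).
    """
    if config is None:
        config = SyntheticConfig()
    if overrides:
        config = SyntheticConfig(**{**config.__dict__, **overrides})
    config.validate()
    rng = np.random.default_rng(config.seed)

    m = len(config.n_per_class)
    labels = np.concatenate(
        [np.full(nk, f"C{k + 1}") for k, nk in enumerate(config.n_per_class)]
    )
    y = np.concatenate([np.full(nk, k) for k, nk in enumerate(config.n_per_class)])
    n = len(labels)

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth: list[str] = []

    for g, (effect, sd) in enumerate(config.planted_single):
        class_means = effect * sd * np.arange(m)
        row = class_means[y] + rng.normal(0.0, sd, n)
        gene_rows.append(row)
        gid = f"S{g + 1:02d}"
        gene_ids.append(gid)
        truth.append(gid)

    for g, flip in enumerate(config.planted_pairs):
        latent = rng.normal(0.0, 1.0, n)
        eps_a = rng.normal(0.0, 1.0, n)
        eps_b = rng.normal(0.0, 1.0, n)
        sign = np.where(y == 0, 1.0, -1.0)  # class C1 prefers gene_a on top
        if flip > 0.0:
            d = np.sqrt(2.0) * float(norm.ppf(1.0 - flip))
            half = 0.5 * sign * d
            row_a = latent + half + eps_a
            row_b = latent - half + eps_b
        else:
            # infinite-offset limit: force the class ordering exactly by
            # reflecting the noise difference where it points the wrong way
            diff = eps_a - eps_b
            diff = sign * np.abs(diff)
            mid = 0.5 * (eps_a + eps_b)
            row_a = latent + mid + 0.5 * diff
            row_b = latent + mid - 0.5 * diff
        ga, gb = f"P{g + 1:02d}a", f"P{g + 1:02d}b"
        gene_rows.extend([row_a, row_b])
        gene_ids.extend([ga, gb])
        truth.extend([ga, gb])

    if config.n_noise_genes:
        noise = rng.normal(0.0, 1.0, (config.n_noise_genes, n))
        gene_rows.extend(noise)
        width = max(4, len(str(config.n_noise_genes)))
        gene_ids.extend(f"N{g + 1:0{width}d}" for g in range(config.n_noise_genes))

    values = np.vstack([np.atleast_2d(r) for r in gene_rows])
    if config.noise_model == "lognormal":
        values = np.exp(values)

    sample_ids = np.array([f"sample{i + 1:03d}" for i in range(n)])

    if config.test_fraction == 0.0:
        train = ExpressionDataset(gene_ids, sample_ids, values, labels)
        return train, None, truth

    test_mask = np.zeros(n, dtype=bool)
    for k, nk in enumerate(config.n_per_class):
        members = np.flatnonzero(y == k)
        n_test = int(round(config.test_fraction * nk))
        n_test = min(max(n_test, 1), nk - 1)  # keep both splits non-empty
        test_mask[rng.permutation(members)[:n_test]] = True

    def build(mask: np.ndarray) -> ExpressionDataset:
        idx = np.flatnonzero(mask)
        return ExpressionDataset(gene_ids, sample_ids[idx], values[:, idx], labels[idx])

    return build(~test_mask), build(test_mask), truth
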