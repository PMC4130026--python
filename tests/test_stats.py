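"""Contingency-table construction, the 0.5 tie rule and the chi-square form."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from irgdc import (
    ExpressionDataset,
    all_pairwise_chi_squares,
    all_single_chi_squares,
    chi_square,
    pairwise_table,
    single_gene_table,
)
from irgdc.stats import chi2_from_counts

from _oracles import mean_split_table, ordering_table, pearson_chi2


def make_ds(rows, labels, gene_ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    gene_ids = gene_ids or [f"g{i}" for i in range(rows.shape[0])]
    return ExpressionDataset(
        gene_ids, [f"s{i}" for i in range(rows.shape[1])], rows, labels
    )


class TestSingleGeneTable:
    def test_clean_split_around_mean(self):
        ds = make_ds([[1, 2, 3, 4]], ["A", "A", "B", "B"])
        t = single_gene_table(ds, "g0")
        assert t.counts.tolist() == [[0, 2], [2, 0]]
        assert t.grand_total == 4

    def test_constant_gene_splits_in_half(self):
        ds = make_ds([[5, 5, 5, 5]], ["A", "A", "B", "B"])
        t = single_gene_table(ds, "g0")
        assert t.counts.tolist() == [[1, 1], [1, 1]]

    def test_matches_enumeration_oracle(self):
        # mean 2.4: one A above/one below, one B above/two below
        ds = make_ds([[1, 3, 2, 2, 4]], ["A", "A", "B", "B", "B"])
        t = single_gene_table(ds, "g0")
        assert t.counts.tolist() == [[1, 1], [1, 2]]
        expected = mean_split_table(ds.values[0], ds.y_, 2)
        assert np.array_equal(t.counts, expected)

    def test_unknown_gene(self, tiny_dataset):
        with pytest.raises(KeyError):
            single_gene_table(tiny_dataset, "nope")


class TestPairwiseTable:
    def test_perfect_class_dependent_reversal(self):
        ds = make_ds([[5, 6, 1, 2], [1, 2, 5, 6]], ["A", "A", "B", "B"])
        t = pairwise_table(ds, "g0", "g1")
        assert t.counts.tolist() == [[2, 0], [0, 2]]

    def test_equal_valued_genes_all_tie(self):
        ds = make_ds([[1, 2, 3, 4], [1, 2, 3, 4]], ["A", "A", "B", "B"])
        t = pairwise_table(ds, "g0", "g1")
        assert t.counts.tolist() == [[1, 1], [1, 1]]

    def test_matches_enumeration_oracle(self):
        ds = make_ds(
            [[3, 1, 4, 2, 5], [2, 2, 4, 3, 1]], ["A", "A", "B", "B", "B"]
        )
        t = pairwise_table(ds, "g0", "g1")
        assert t.counts.tolist() == [[1, 1], [1.5, 1.5]]
        expected = ordering_table(ds.values[0], ds.values[1], ds.y_, 2)
        assert np.array_equal(t.counts, expected)

    def test_identical_gene_ids_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            pairwise_table(tiny_dataset, "g1", "g1")


class TestChiSquare:
    def test_perfect_association_equals_n(self):
        assert chi_square(np.array([[5.0, 0.0], [0.0, 5.0]])) == pytest.approx(10.0)

    def test_independence_is_zero(self):
        assert chi_square(np.array([[5.0, 5.0], [5.0, 5.0]])) == pytest.approx(0.0)

    def test_matches_scipy_pearson_on_integer_table(self):
        counts = np.array([[3.0, 1.0], [2.0, 4.0]])
        expected = chi2_contingency(counts, correction=False).statistic
        assert chi_square(counts) == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_cells_contribute_nothing(self):
        # empty row and empty column: statistic stays finite, matches Pearson
        counts = np.array([[2.0, 0.0], [3.0, 0.0], [0.0, 0.0]])
        assert chi_square(counts) == pytest.approx(pearson_chi2(counts), abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            chi_square(np.zeros((2, 2)))

    @given(
        counts=st.lists(
            st.lists(
                st.floats(0, 20).map(lambda v: round(v * 2) / 2), min_size=2, max_size=2
            ),
            min_size=2,
            max_size=6,
        ).filter(lambda rows: sum(map(sum, rows)) > 0)
    )
    @settings(max_examples=150, deadline=None)
    def test_marginal_form_equals_pearson_form(self, counts):
        """N(sum f^2/(n_k T_q) - 1) is the Pearson statistic, fractional counts included."""
        counts = np.array(counts)
        ours = chi_square(counts)
        ref = pearson_chi2(counts)
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-9)
        assert ours >= -1e-9


class TestInvariantsAndBatches:
    def test_tables_conserve_sample_mass(self, random_dataset):
        ds = random_dataset
        for gene in ds.gene_ids[:4]:
            assert single_gene_table(ds, gene).grand_total == ds.n_samples
        t = pairwise_table(ds, "g00", "g01")
        assert t.grand_total == ds.n_samples
        assert np.allclose(t.row_totals, np.bincount(ds.y_, minlength=ds.n_classes))

    def test_permuting_samples_changes_nothing(self, random_dataset, rng):
        ds = random_dataset
        perm = rng.permutation(ds.n_samples)
        shuffled = ds.subset_samples(perm)
        for gene in ds.gene_ids[:3]:
            assert np.array_equal(
                single_gene_table(ds, gene).counts,
                single_gene_table(shuffled, gene).counts,
            )
        assert np.array_equal(
            pairwise_table(ds, "g02", "g05").counts,
            pairwise_table(shuffled, "g02", "g05").counts,
        )

    def test_batch_single_matches_per_gene_loop(self, random_dataset):
        ds = random_dataset
        batched = all_single_chi_squares(ds)
        for gene in ds.gene_ids:
            assert batched[gene] == pytest.approx(
                chi_square(single_gene_table(ds, gene)), rel=1e-12
            )

    def test_batch_pairwise_matches_loop_and_is_symmetric(self, random_dataset):
        ds = random_dataset
        genes = ds.gene_ids[:6].tolist()
        batched = all_pairwise_chi_squares(ds, genes)
        assert len(batched) == 6 * 5  # both orderings of 15 unordered pairs
        for (a, b), val in batched.items():
            assert val == batched[(b, a)]
            assert val == pytest.approx(
                chi_square(pairwise_table(ds, a, b)), rel=1e-12, abs=1e-12
            )

    def test_pairwise_needs_two_genes(self, random_dataset):
        with pytest.raises(ValueError):
            all_pairwise_chi_squares(random_dataset, ["g00"])

    def test_pairwise_invariant_to_within_sample_monotone_transform(self, random_dataset):
        ds = random_dataset
        before = pairwise_table(ds, "g00", "g01").counts
        transformed = ExpressionDataset(
            ds.gene_ids, ds.sample_ids, np.exp(ds.values * 1.7), ds.labels
        )
        assert np.array_equal(before, pairwise_table(transformed, "g00", "g01").counts)

    def test_single_gene_not_invariant_counterexample(self):
        """A per-sample monotone distortion moves the mean split: the
        mean-split statistic is *not* a relative-expression statistic."""
        ds = make_ds([[1, 2, 3, 4]], ["A", "B", "A", "B"])
        base = chi_square(single_gene_table(ds, "g0"))
        # inflate one sample only: within-sample ordering is untouched
        distorted = ds.values.copy()
        distorted[:, 3] *= 100
        ds2 = make_ds(distorted, ["A", "B", "A", "B"])
        assert chi_square(single_gene_table(ds2, "g0")) != pytest.approx(base)

    def test_zero_iff_rows_proportional_to_column_totals(self):
        proportional = np.array([[2.0, 6.0], [1.0, 3.0], [3.0, 9.0]])
        assert chi_square(proportional) == pytest.approx(0.0, abs=1e-12)
        skewed = proportional.copy()
        skewed[0] = [6.0, 2.0]
        assert chi_square(skewed) > 0.1

    def test_tie_tolerance_flag_declares_near_ties(self):
        ds = make_ds([[1.0, 2.0, 3.0, 4.0], [1.05, 1.8, 3.02, 4.5]], ["A", "A", "B", "B"])
        strict = pairwise_table(ds, "g0", "g1")
        loose = pairwise_table(ds, "g0", "g1", tie_tol=0.1)
        assert strict.counts.sum() == loose.counts.sum() == 4
        assert not np.array_equal(strict.counts, loose.counts)
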