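import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enclasc import (
    SimulationConfig,
    compute_gene_scores,
    corrupt_dropout,
    make_rare_class_split,
    simulate,
)


class TestSimulate:
    def test_balanced_proportions_split_exactly(self):
        config = SimulationConfig(
            n_cells=100, n_genes=50, class_proportions=(0.5, 0.5),
            n_marker_genes_per_class=5, seed=0,
        )
        data = simulate(config)
        assert data.labels.count("type_0") == 50
        assert data.labels.count("type_1") == 50

    def test_reproducible_from_seed(self):
        config = SimulationConfig(
            n_cells=80, n_genes=40, n_marker_genes_per_class=4, seed=3
        )
        a, b = simulate(config), simulate(config)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.labels == b.labels

    def test_tiny_proportion_errors(self):
        config = SimulationConfig(
            n_cells=10, class_proportions=(0.999, 0.001),
            n_marker_genes_per_class=5,
        )
        with pytest.raises(ValueError, match="too small"):
            simulate(config)

    def test_zero_fraction_matches_negative_binomial_mass_without_dropout(self):
        """With the dropout temperature sent to zero (midpoint 0), observed
        zeros come from the counting noise alone: P(0) = (1 + mu/theta)^-theta."""
        theta = 2.0
        config = SimulationConfig(
            n_cells=4000,
            n_genes=40,
            class_proportions=(1.0,),
            n_marker_genes_per_class=0,
            class_profile_sigma=0.0,
            library_size_sigma=0.0,
            dispersion=theta,
            dropout_midpoint=0.0,
            dropout_steepness=1e-9,
            seed=21,
        )
        data = simulate(config)
        from enclasc.synthetic_data import class_mean_matrix

        mu = class_mean_matrix(config)[0]
        expected = (1.0 + mu / theta) ** (-theta)
        observed = (data.values == 0).mean(axis=0)
        # Monte-Carlo tolerance: 4 sigma of a binomial proportion
        tol = 4 * np.sqrt(expected * (1 - expected) / config.n_cells) + 1e-3
        assert (np.abs(observed - expected) <= tol).all()

    def test_marker_genes_rank_high_in_dispersion_residual(self):
        hits = []
        for seed in (0, 1, 2):
            config = SimulationConfig(
                n_cells=400, n_genes=200, n_marker_genes_per_class=8, seed=seed
            )
            data = simulate(config)
            scores, _ = compute_gene_scores(data)
            n_markers = 8 * len(config.class_proportions)
            markers = {f"gene_{j}" for j in range(n_markers)}
            marker_df2 = scores.loc[sorted(markers), "dF2"].mean()
            other_df2 = scores.drop(index=sorted(markers))["dF2"].mean()
            hits.append(marker_df2 > other_df2)
        assert all(hits)


class TestCorruptDropout:
    def test_zero_fraction_is_identity(self, toy_dataset):
        out = corrupt_dropout(toy_dataset, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, toy_dataset.values)

    def test_exact_count_of_entries_zeroed(self):
        rng = np.random.default_rng(0)
        from enclasc import ExpressionDataset

        values = rng.poisson(4.0, size=(20, 20)).astype(float)
        values[values == 0] = 1.0  # make nnz exactly 400
        data = ExpressionDataset(
            values, [f"g{j}" for j in range(20)], [f"c{i}" for i in range(20)]
        )
        out = corrupt_dropout(data, 0.5, seed=2)
        assert int((out.values == 0).sum()) == 200

    def test_full_fraction_empties_matrix(self, toy_dataset):
        out = corrupt_dropout(toy_dataset, 1.0, seed=3)
        assert not out.values.any()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(fraction=st.floats(0.0, 1.0), seed=st.integers(0, 1000))
    def test_never_touches_zeros_names_or_labels(self, fraction, seed):
        data = simulate(
            SimulationConfig(
                n_cells=30, n_genes=20, n_marker_genes_per_class=2, seed=9
            )
        )
        out = corrupt_dropout(data, fraction, seed=seed)
        was_zero = data.values == 0
        assert (out.values[was_zero] == 0).all()
        changed = out.values != data.values
        assert (out.values[changed] == 0).all()
        assert out.gene_names == data.gene_names
        assert out.labels == data.labels
        nnz = int((data.values != 0).sum())
        assert int((out.values == 0).sum() - was_zero.sum()) == int(
            np.floor(fraction * nnz)
        )

    def test_observed_sparsity_increases_with_fraction(self):
        config = SimulationConfig(
            n_cells=100, n_genes=60, n_marker_genes_per_class=6, seed=5
        )
        data = simulate(config)
        zero_fracs = [
            (corrupt_dropout(data, f, seed=6).values == 0).mean()
            for f in (0.0, 0.1, 0.3, 0.5)
        ]
        assert all(a < b for a, b in zip(zero_fracs, zero_fracs[1:]))


class TestRareClassSplit:
    def test_counts_match_requested_fractions(self):
        reference, query = make_rare_class_split(
            n_reference=5000, n_query=1000, seed=0
        )
        assert reference.n_cells == 5000 and query.n_cells == 1000
        assert reference.labels.count("type_0") == 20  # 0.4% of 5000
        assert query.labels.count("type_0") == 300  # 30% of 1000

    def test_designated_class_is_few_sample(self):
        from enclasc import identify_few_sample_classes

        reference, _ = make_rare_class_split(seed=1)
        rare = identify_few_sample_classes(reference.labels)
        assert "type_0" in rare

    def test_splits_are_disjoint_and_exhaustive(self):
        reference, query = make_rare_class_split(
            n_reference=2000, n_query=500, seed=2
        )
        ids = reference.cell_ids + query.cell_ids
        assert len(ids) == len(set(ids)) == 2500

    def test_reproducible(self):
        a_ref, a_qry = make_rare_class_split(seed=4)
        b_ref, b_qry = make_rare_class_split(seed=4)
        np.testing.assert_array_equal(a_ref.values, b_ref.values)
        assert a_qry.labels == b_qry.labels
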