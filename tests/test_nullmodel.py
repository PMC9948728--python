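import numpy as np
import pandas as pd
import pytest

from assemblage.diversity import dissimilarity_matrix
from assemblage.nullmodel import (
    StochasticityPartition,
    dirichlet_alpha,
    expected_dissimilarity,
    neutral_draw,
    partition_stochasticity,
    regional_weights,
)
from assemblage.tables import CommunityTable


def _table(counts, sites=None):
    frame = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(len(counts))],
        columns=[f"t{k}" for k in range(len(counts[0]))],
    )
    return CommunityTable(frame, sites or ["x"] * len(counts))


class TestRegionalWeights:
    def test_single_occupant_taxon_takes_all_frequency(self):
        table = _table([[5, 0], [3, 0]])
        # zero-total taxa are implicitly absent; w_f concentrates on t0
        w = regional_weights(table)
        assert w.w_f["t0"] == pytest.approx(1.0)

    def test_equal_occupancy_and_totals_split_evenly(self):
        table = _table([[2, 2], [3, 3]])
        w = regional_weights(table)
        np.testing.assert_allclose(w.w_f, [0.5, 0.5])
        np.testing.assert_allclose(w.w_a, [0.5, 0.5])

    def test_matches_two_line_oracle(self, random_community):
        w = regional_weights(random_community)
        c = random_community.counts.to_numpy()
        occ = (c > 0).mean(axis=0)
        np.testing.assert_allclose(w.w_f, occ / occ.sum(), atol=1e-12)
        np.testing.assert_allclose(w.w_a, c.sum(0) / c.sum(), atol=1e-12)

    def test_weights_sum_to_one(self, random_community):
        w = regional_weights(random_community)
        assert w.w_f.sum() == pytest.approx(1.0, abs=1e-12)
        assert w.w_a.sum() == pytest.approx(1.0, abs=1e-12)


class TestNeutralDraw:
    def test_full_richness_includes_every_taxon(self, random_community, rng):
        w = regional_weights(random_community)
        t = random_community.n_taxa
        chosen, abund = neutral_draw(t, w, rng)
        assert sorted(chosen) == list(range(t))
        assert abund.sum() == pytest.approx(1.0, abs=1e-12)

    def test_alpha_is_weights_over_min(self):
        np.testing.assert_allclose(
            dirichlet_alpha([0.2, 0.3, 0.5]), [1.0, 1.5, 2.5]
        )

    def test_richness_bounds_enforced(self, random_community, rng):
        w = regional_weights(random_community)
        with pytest.raises(ValueError):
            neutral_draw(0, w, rng)
        with pytest.raises(ValueError):
            neutral_draw(random_community.n_taxa + 1, w, rng)

    def test_dirichlet_means_match_alpha_moments(self, rng):
        """Empirical Dirichlet(alpha) means converge to alpha/sum(alpha)."""
        alpha = dirichlet_alpha([0.2, 0.3, 0.5])
        n = 10_000
        draws = rng.dirichlet(alpha, size=n)
        expect = alpha / alpha.sum()
        se = draws.std(axis=0, ddof=1) / np.sqrt(n)
        assert (np.abs(draws.mean(axis=0) - expect) <= 3 * se).all()

    def test_single_taxon_degenerate_simplex(self, random_community, rng):
        w = regional_weights(random_community)
        chosen, abund = neutral_draw(1, w, rng)
        assert len(chosen) == 1
        np.testing.assert_array_equal(abund, [1.0])


class TestExpectedDissimilarity:
    def test_one_simulation_equals_its_matrix(self, random_community):
        w = regional_weights(random_community)
        a = expected_dissimilarity(random_community, w, 1, "sorensen", seed=9)
        b = expected_dissimilarity(random_community, w, 1, "sorensen", seed=9)
        pd.testing.assert_frame_equal(a, b)
        vals = a.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_single_taxon_pool_gives_zero_sorensen(self):
        table = _table([[10], [7], [3]])
        w = regional_weights(table)
        e = expected_dissimilarity(table, w, 5, "sorensen", seed=0)
        np.testing.assert_allclose(e.to_numpy(), 0.0)

    def test_stable_across_seed_batches(self, random_community):
        """Entry means vary by < 0.02 sd across 10 independent seed batches."""
        w = regional_weights(random_community)
        mats = [
            expected_dissimilarity(
                random_community, w, 1000, "sorensen", seed=s
            ).to_numpy()
            for s in range(10)
        ]
        sd = np.std([m.mean() for m in mats], ddof=1)
        assert sd < 0.02

    def test_bray_curtis_diag_zero_and_symmetric(self, random_community):
        w = regional_weights(random_community)
        e = expected_dissimilarity(random_community, w, 20, "bray_curtis", seed=4)
        v = e.to_numpy()
        assert np.allclose(np.diag(v), 0)
        assert np.allclose(v, v.T)


class TestPartition:
    def test_equal_matrices_fully_stochastic(self):
        o = pd.DataFrame(np.full((3, 3), 0.4) - 0.4 * np.eye(3))
        comp = partition_stochasticity(o, o.copy())
        assert (comp.stoch.to_numpy() == 1.0).all()
        assert (comp.det_a.to_numpy() == 0.0).all()
        assert (comp.det_b.to_numpy() == 0.0).all()

    def test_observed_above_expected(self):
        o = pd.DataFrame([[0.0, 0.8], [0.8, 0.0]])
        e = pd.DataFrame([[0.0, 0.6], [0.6, 0.0]])
        comp = partition_stochasticity(o, e)
        assert comp.det_a.iloc[0, 1] == pytest.approx(0.25)  # (0.8-0.6)/0.8
        assert comp.stoch.iloc[0, 1] == pytest.approx(0.75)
        assert comp.det_b.iloc[0, 1] == 0.0

    def test_observed_below_expected(self):
        o = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]])
        e = pd.DataFrame([[0.0, 0.6], [0.6, 0.0]])
        comp = partition_stochasticity(o, e)
        assert comp.det_b.iloc[0, 1] == pytest.approx(1 / 3)  # (0.6-0.4)/(1-0.4)
        assert comp.stoch.iloc[0, 1] == pytest.approx(2 / 3)
        assert comp.det_a.iloc[0, 1] == 0.0

    def test_observed_one_uses_det_a_branch(self):
        o = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]])
        e = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]])
        comp = partition_stochasticity(o, e)
        assert comp.det_a.iloc[0, 1] == pytest.approx(0.5)
        assert np.isfinite(comp.stoch.to_numpy()).all()

    def test_components_sum_to_one_and_bounded(self, rng):
        n = 10
        o = rng.random((n, n))
        o = (o + o.T) / 2
        np.fill_diagonal(o, 0)
        e = rng.random((n, n))
        e = (e + e.T) / 2
        np.fill_diagonal(e, 0)
        comp = partition_stochasticity(pd.DataFrame(o), pd.DataFrame(e))
        total = (
            comp.stoch.to_numpy() + comp.det_a.to_numpy() + comp.det_b.to_numpy()
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        for frame in (comp.stoch, comp.det_a, comp.det_b):
            v = frame.to_numpy()
            assert ((v >= -1e-12) & (v <= 1 + 1e-12)).all()

    def test_sample_means_exclude_diagonal(self):
        o = pd.DataFrame([[0.0, 0.8], [0.8, 0.0]])
        e = pd.DataFrame([[0.0, 0.6], [0.6, 0.0]])
        comp = partition_stochasticity(o, e)
        means = comp.sample_means()
        # with the diagonal excluded each column has a single 0.75 entry
        np.testing.assert_allclose(means["stoch"], 0.75)


class TestStochasticityPartitionModel:
    def test_deterministic_given_seed(self, random_community):
        a = StochasticityPartition(random_community, "sorensen").fit(50, seed=3)
        b = StochasticityPartition(random_community, "sorensen").fit(50, seed=3)
        pd.testing.assert_frame_equal(a.summary(), b.summary())

    def test_observed_matrix_matches_direct_computation(self, random_community):
        res = StochasticityPartition(random_community, "bray_curtis").fit(5, seed=1)
        direct = dissimilarity_matrix(random_community, "bray_curtis")
        pd.testing.assert_frame_equal(res.components.observed, direct)

    def test_branch_average_between_zero_and_one(self, random_community):
        res = StochasticityPartition(random_community, "sorensen").fit(50, seed=2)
        branch = res.components.sample_means_branch_averaged()
        assert ((branch >= 0) & (branch <= 1)).all()
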