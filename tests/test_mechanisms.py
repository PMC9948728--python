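import numpy as np
import pandas as pd
import pytest

from assemblage.mechanisms import (
    MechanismBattery,
    dispersal_weights,
    environmental_weights,
    neutral_abundance_weights,
    neutral_frequency_weights,
    run_battery,
    simulate_community,
    weight_correlation,
)
from assemblage.tables import CommunityTable


def _table(counts, sites=None):
    frame = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(len(counts))],
        columns=[f"t{k}" for k in range(len(counts[0]))],
    )
    return CommunityTable(frame, sites or ["x"] * len(counts))


def _distances(values, ids):
    return pd.DataFrame(values, index=ids, columns=ids)


class TestDispersalWeights:
    def test_equal_distances_give_arithmetic_mean(self):
        table = _table([[4, 0], [2, 2], [0, 4]])
        d = np.full((3, 3), 7.0)
        np.fill_diagonal(d, 0.0)
        w = dispersal_weights(table, _distances(d, table.sample_ids))
        # sample 0: mean of (0.5, 0.5) and (0, 1) relative abundances
        np.testing.assert_allclose(w.values.loc["s0"], [0.25, 0.75])

    def test_taxon_absent_elsewhere_gets_zero(self):
        table = _table([[4, 1], [5, 0], [5, 0]])
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        w = dispersal_weights(table, _distances(d, table.sample_ids))
        assert w.values.loc["s1", "t1"] == pytest.approx(1 / (2 * 5))
        assert w.values.loc["s2", "t1"] == pytest.approx(1 / (2 * 5))
        # for sample 0, t1 occurs nowhere else
        assert w.values.loc["s0", "t1"] == 0.0

    def test_hand_worked_two_source_example(self):
        # sources at d=1 and d=2 with x=0.3 and 0.6: (1*0.3 + 0.5*0.6)/1.5 = 0.4
        table = _table([[0, 10], [3, 7], [6, 4]])
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.5], [2.0, 1.5, 0.0]])
        w = dispersal_weights(table, _distances(d, table.sample_ids))
        assert w.values.loc["s0", "t0"] == pytest.approx(0.4)

    def test_matches_double_loop_oracle(self, rng):
        n, t = 10, 8
        counts = rng.integers(0, 50, size=(n, t))
        counts[:, 0] += 1  # positive row sums
        table = _table(counts.tolist())
        pts = rng.random((n, 2)) * 40
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        w = dispersal_weights(table, _distances(d, table.sample_ids))
        x = counts / counts.sum(axis=1, keepdims=True)
        for i in range(n):
            for k in range(t):
                num = sum(
                    (1.0 / d[i, j]) * x[j, k] for j in range(n) if j != i
                )
                den = sum(1.0 / d[i, j] for j in range(n) if j != i)
                assert w.values.iloc[i, k] == pytest.approx(num / den, abs=1e-12)

    def test_zero_distance_floored(self):
        table = _table([[4, 0], [2, 2], [0, 4]], sites=["a", "a", "b"])
        d = np.array([[0.0, 0.0, 10.0], [0.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        w = dispersal_weights(table, _distances(d, table.sample_ids))
        assert w.provenance["distance_floor_km"] == pytest.approx(5.0)
        assert np.isfinite(w.values.to_numpy()).all()

    def test_single_sample_rejected(self):
        table = _table([[5]])
        with pytest.raises(ValueError):
            dispersal_weights(table, _distances(np.zeros((1, 1)), table.sample_ids))


class TestEnvironmentalWeights:
    def test_always_present_taxon_gets_probability_one(self, rng):
        table = _table([[3, 1], [4, 0], [2, 3], [5, 0]])
        env = pd.DataFrame({"PC1": rng.normal(size=4)}, index=table.sample_ids)
        w = environmental_weights(table, env, seed=0)
        np.testing.assert_allclose(w.values["t0"], 1.0)

    def test_probabilities_bounded(self, random_community, rng):
        env = pd.DataFrame(
            rng.normal(size=(random_community.n_samples, 2)),
            index=random_community.sample_ids,
            columns=["PC1", "PC2"],
        )
        w = environmental_weights(random_community, env, seed=0)
        v = w.values.to_numpy()
        assert ((v >= 0) & (v <= 1)).all()

    def test_separable_taxon_recovered(self, rng):
        """A taxon present iff PC1 > 0 (wide margin) gets clearly higher
        predicted occurrence probability where PC1 > 0, across 10 seeds."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            pc1 = np.concatenate([r.uniform(0.5, 2.0, 43), r.uniform(-2.0, -0.5, 43)])
            presence = (pc1 > 0).astype(int)
            counts = np.column_stack(
                [presence * (1 + r.integers(0, 9, 86)), 1 + r.integers(0, 9, 86)]
            )
            table = _table(counts.tolist())
            env = pd.DataFrame({"PC1": pc1}, index=table.sample_ids)
            w = environmental_weights(table, env, seed=seed)
            p = w.values["t0"].to_numpy()
            if p[pc1 > 0].mean() - p[pc1 < 0].mean() > 0.5:
                hits += 1
        assert hits >= 9


class TestSimulateCommunity:
    def test_one_hot_weights_single_taxon(self, rng):
        chosen, abund = simulate_community(
            np.array([0.0, 1.0, 0.0]), np.array([0.2, 0.5, 0.3]), 1, rng
        )
        assert list(chosen) == [1]
        np.testing.assert_array_equal(abund, [1.0])

    def test_richness_respected(self, rng):
        w = rng.random(12)
        chosen, abund = simulate_community(w, w, 7, rng)
        assert len(chosen) == 7
        assert len(np.unique(chosen)) == 7
        assert abund.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dirichlet_means_track_abundance_weights(self, rng):
        """Over many draws the mean simulated abundances approach the
        Dirichlet moments alpha/sum(alpha) of the abundance weights."""
        ow = np.ones(3)
        aw = np.array([0.2, 0.3, 0.5])
        n = 10_000
        sums = np.zeros(3)
        sq = np.zeros(3)
        for _ in range(n):
            chosen, abund = simulate_community(ow, aw, 3, rng)
            full = np.zeros(3)
            full[chosen] = abund
            sums += full
            sq += full**2
        mean = sums / n
        sd = np.sqrt(sq / n - mean**2)
        expect = aw / aw.sum()
        assert (np.abs(mean - expect) <= 3 * sd / np.sqrt(n) + 1e-3).all()

    def test_fallback_to_regional_frequencies(self, rng):
        ow = np.array([1.0, 0.0, 0.0, 0.0])
        fw = np.array([0.1, 0.3, 0.3, 0.3])
        chosen, _ = simulate_community(ow, np.ones(4), 3, rng, fallback_weights=fw)
        assert 0 in chosen
        assert len(chosen) == 3

    def test_insufficient_weights_without_fallback_raise(self, rng):
        with pytest.raises(ValueError, match="fallback"):
            simulate_community(np.array([1.0, 0.0]), np.ones(2), 2, rng)


class TestBattery:
    def _weights(self, table, rng):
        n = table.n_samples
        d = rng.random((n, n)) * 20 + 1
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dmat = _distances(d, table.sample_ids)
        env = pd.DataFrame(
            rng.normal(size=(n, 2)), index=table.sample_ids, columns=["PC1", "PC2"]
        )
        return {
            "w_f": neutral_frequency_weights(table),
            "w_a": neutral_abundance_weights(table),
            "w_d": dispersal_weights(table, dmat),
            "w_e": environmental_weights(table, env, seed=1),
        }

    def test_reproducible_and_bounded(self, random_community, rng):
        weights = self._weights(random_community, rng)
        a = run_battery(random_community, weights, n_sims=10, seed=5)
        b = run_battery(random_community, weights, n_sims=10, seed=5)
        for sa, sb in zip(a, b):
            assert sa.mean_dissim == sb.mean_dissim
            assert 0.0 <= sa.mean_dissim <= 1.0

    def test_all_seven_processes_scored_twice(self, random_community, rng):
        weights = self._weights(random_community, rng)
        scores = run_battery(random_community, weights, n_sims=5, seed=0)
        assert len(scores) == 14  # 7 processes x 2 metrics
        assert len({s.process for s in scores}) == 7

    def test_sorensen_depends_only_on_occurrence_rule(self, random_community, rng):
        """Processes sharing an occurrence rule have equal Sorensen
        expectations (abundance stage never touches presence/absence)."""
        weights = self._weights(random_community, rng)
        scores = run_battery(random_community, weights, n_sims=400, seed=8)
        by_occ = {}
        for s in scores:
            if s.metric == "sorensen":
                by_occ.setdefault(s.occurrence_rule, []).append(s.mean_dissim)
        for occ, vals in by_occ.items():
            assert max(vals) - min(vals) < 0.02, (occ, vals)

    def test_weight_correlation_finite(self, random_community, rng):
        weights = self._weights(random_community, rng)
        r = weight_correlation(weights["w_d"], weights["w_e"])
        assert -1.0 <= r <= 1.0


class TestMechanismBatteryModel:
    def test_summary_ranks_processes(self, random_community, rng):
        n = random_community.n_samples
        d = rng.random((n, n)) * 30 + 1
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        env = pd.DataFrame(
            rng.normal(size=(n, 2)),
            index=random_community.sample_ids,
            columns=["PC1", "PC2"],
        )
        model = MechanismBattery(
            random_community,
            _distances(d, random_community.sample_ids),
            env,
            classifier_seed=0,
        )
        res = model.fit(n_sims=20, seed=1)
        table = res.summary()
        assert table.shape == (7, 2)
        assert res.best_process("bray_curtis") == table["bray_curtis"].idxmin()
        per_sample = res.sample_scores("sorensen")
        assert per_sample.shape == (n, 7)
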