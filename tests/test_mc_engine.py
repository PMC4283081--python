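"""Class sampling, cost draws, the ensemble and the total-cost identity."""

import numpy as np
import pytest
from scipy import stats

from gms_costsim.mc_engine import (
    SimulationSpec,
    class_distribution,
    draw_cost,
    sample_stratum,
    simulate,
    total_cost,
)
from gms_costsim.strata import (Cohort, Gender, RateTable, Region,
                                StratumKey, all_strata)



EASTERN_M_0_11 = StratumKey(Region.EASTERN, Gender.MALE, Cohort.C0_11)

STRATA = list(all_strata())


def _three_class_dist(w=(20, 30, 50)):
    eligible = {STRATA[i]: w[i] for i in range(3)}
    return class_distribution(eligible), [STRATA[i] for i in range(3)]


class TestClassDistribution:
    def test_single_class(self):
        dist = class_distribution({EASTERN_M_0_11: 42})
        assert list(dist.cumulative) == [1.0]
        assert dist.probability(EASTERN_M_0_11) == 1.0

    def test_forced_arithmetic_20_30_50(self):
        dist, _ = _three_class_dist()
        assert np.allclose(dist.cumulative, [0.2, 0.5, 1.0])
        assert dist.cumulative[-1] == 1.0

    def test_uniform_weights_over_full_universe(self):
        dist = class_distribution({k: 7 for k in STRATA})
        assert np.allclose(dist.probabilities, 1 / 160)
        assert dist.cumulative[-1] == 1.0

    def test_zero_weight_class_retained_with_zero_width(self):
        dist = class_distribution({STRATA[0]: 0, STRATA[1]: 10})
        assert dist.probabilities[0] == 0.0
        assert dist.cumulative[0] == 0.0  # zero-width interval

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            class_distribution({k: 0 for k in STRATA[:5]})


class TestSampleStratum:
    def test_zero_maps_to_first_nonzero_class(self):
        dist = class_distribution({STRATA[0]: 0, STRATA[1]: 5, STRATA[2]: 5})
        assert sample_stratum(0.0, dist) == STRATA[1]

    def test_interval_lookup(self):
        dist, keys = _three_class_dist()
        assert sample_stratum(0.49, dist) == keys[1]
        assert sample_stratum(0.19, dist) == keys[0]
        assert sample_stratum(0.5, dist) == keys[2]   # half-open bounds
        assert sample_stratum(0.999, dist) == keys[2]

    @pytest.mark.parametrize("u", [-0.01, 1.0, 1.5])
    def test_u_domain(self, u):
        dist, _ = _three_class_dist()
        with pytest.raises(ValueError, match=r"\[0, 1\)"):
            sample_stratum(u, dist)

    def test_frequencies_match_probabilities_chi_square(self):
        dist, keys = _three_class_dist()
        rng = np.random.default_rng(2024)
        u = rng.random(100_000)
        idx = np.searchsorted(dist.cumulative, u, side="right")
        observed = np.bincount(idx, minlength=3)
        _, p = stats.chisquare(observed, f_exp=np.array([0.2, 0.3, 0.5]) * 100_000)
        assert p > 0.01


class TestDrawCost:
    def _tables(self, uniform_table, cov=0.5, cr=1.0, ac=10.0):
        return (uniform_table("coverage", cov), uniform_table("claims_rate", cr),
                uniform_table("avg_cost", ac))

    def test_noise_free_deterministic_core(self, uniform_table):
        cov, cr, ac = self._tables(uniform_table)
        rng = np.random.default_rng(0)
        assert draw_cost(EASTERN_M_0_11, cov, cr, ac, 0.0, rng) == 5.0

    def test_zero_coverage_rejected(self, uniform_table):
        cov, cr, ac = self._tables(uniform_table, cov=0.0)
        with pytest.raises(ValueError, match="zero sampling weight"):
            draw_cost(EASTERN_M_0_11, cov, cr, ac, 0.05, np.random.default_rng(0))

    def test_relative_sd_is_five_percent(self, uniform_table):
        cov, cr, ac = self._tables(uniform_table, ac=100.0)
        rng = np.random.default_rng(7)
        draws = np.array([draw_cost(EASTERN_M_0_11, cov, cr, ac, 0.05, rng)
                          for _ in range(20_000)])
        cv = draws.std(ddof=1) / draws.mean()
        assert cv == pytest.approx(0.05, abs=0.001)
        assert (draws > 0).all()


class TestSimulate:
    def _inputs(self, uniform_table, cov=0.5, cr=1.0, ac=10.0, eligible=None):
        eligible = eligible if eligible is not None else {k: 100 for k in STRATA}
        return (eligible, uniform_table("coverage", cov),
                uniform_table("claims_rate", cr), uniform_table("avg_cost", ac))

    def test_single_draw_single_class_no_noise(self, uniform_table):
        eligible = {EASTERN_M_0_11: 50}
        args = self._inputs(uniform_table, eligible=eligible)
        spec = SimulationSpec(horizon=2016, n_iterations=1, noise_sd_fraction=0.0, seed=3)
        res = simulate(spec, *args)
        assert len(res) == 1
        assert res.costs[0] == 5.0
        assert res.deterministic_expectation == 5.0

    def test_reproducibility_identical_draws(self, uniform_table):
        args = self._inputs(uniform_table)
        spec = lambda: SimulationSpec(horizon=2016, n_iterations=5000, seed=99)
        a, b = simulate(spec(), *args), simulate(spec(), *args)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.stratum_index, b.stratum_index)

    def test_ensemble_mean_converges_at_root_n(self, uniform_table):
        # unbiasedness: |mean - E| shrinks ~ 1/sqrt(n) and stays within 3 SE
        eligible = {k: (i % 7 + 1) * 100 for i, k in enumerate(STRATA)}
        cov = RateTable("coverage", {k: 0.2 + 0.6 * (i % 5) / 4 for i, k in enumerate(STRATA)})
        cr = uniform_table("claims_rate", 0.95)
        ac = RateTable("avg_cost", {k: 100.0 + 10.0 * (i % 11) for i, k in enumerate(STRATA)})
        for n in (1_000, 10_000, 100_000):
            spec = SimulationSpec(horizon=2016, n_iterations=n, seed=5)
            res = simulate(spec, eligible, cov, cr, ac)
            se = res.costs.std(ddof=1) / np.sqrt(n)
            assert abs(res.costs.mean() - res.deterministic_expectation) < 3 * se

    def test_positive_weight_zero_cost_class_rejected(self, uniform_table):
        eligible = {k: 100 for k in STRATA}
        cov_vals = {k: 0.5 for k in STRATA}
        cov_vals[EASTERN_M_0_11] = 0.0
        args = (eligible, RateTable("coverage", cov_vals),
                uniform_table("claims_rate", 1.0), uniform_table("avg_cost", 10.0))
        spec = SimulationSpec(horizon=2016, n_iterations=10, seed=1)
        with pytest.raises(ValueError, match="positive sampling weight"):
            simulate(spec, *args)

    def test_seed_mandatory(self, uniform_table):
        args = self._inputs(uniform_table)
        with pytest.raises(ValueError, match="seed"):
            simulate(SimulationSpec(horizon=2016, n_iterations=10), *args)

    def test_sampling_frequencies_full_universe(self, uniform_table):
        eligible = {k: (i % 4 + 1) * 50 for i, k in enumerate(STRATA)}
        args = self._inputs(uniform_table, eligible=eligible)
        spec = SimulationSpec(horizon=2016, n_iterations=100_000, seed=8)
        res = simulate(spec, *args)
        observed = np.bincount(res.stratum_index, minlength=160)
        from gms_costsim.mc_engine import class_distribution
        dist = class_distribution(eligible)
        _, p = stats.chisquare(observed, f_exp=dist.probabilities * spec.n_iterations)
        assert p > 0.01


class TestTotalCost:
    def test_single_stratum_arithmetic(self, uniform_table):
        cov = uniform_table("coverage", 0.5)
        cr = uniform_table("claims_rate", 1.0)
        ac = uniform_table("avg_cost", 10.0)
        assert total_cost({EASTERN_M_0_11: 100}, cov, cr, ac) == 500.0

    def test_matches_brute_force_summation(self, uniform_table):
        rng = np.random.default_rng(4)
        cov = RateTable("coverage", {k: float(rng.uniform(0.1, 0.9)) for k in STRATA})
        cr = RateTable("claims_rate", {k: float(rng.uniform(0.8, 1.0)) for k in STRATA})
        ac = RateTable("avg_cost", {k: float(rng.uniform(100, 1500)) for k in STRATA})
        pop = {k: int(rng.integers(100, 10_000)) for k in STRATA}
        brute = 0.0
        for k in STRATA:
            brute += pop[k] * cov[k] * cr[k] * ac[k]
        assert total_cost(pop, cov, cr, ac) == pytest.approx(brute, abs=0.01)

    def test_scale_identity_with_population_share_expectation(self, uniform_table):
        cov = uniform_table("coverage", 0.4)
        cr = uniform_table("claims_rate", 0.9)
        ac = uniform_table("avg_cost", 100.0)
        pop = {k: 250 for k in STRATA}
        from gms_costsim.mc_engine import class_distribution
        dist = class_distribution(pop)
        per_person = float(np.dot(dist.probabilities,
                                  [cov[k] * cr[k] * ac[k] for k in dist.strata]))
        assert total_cost(pop, cov, cr, ac) == pytest.approx(per_person * sum(pop.values()))
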