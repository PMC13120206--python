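"""Monte Carlo engine: propagation, probabilities, sensitivity."""

import math

import numpy as np
import pytest
from scipy.stats import norm

import sedrisk as sr
from sedrisk.distributions import DistributionSpec
from sedrisk.indices import IGEO_SCHEME
from sedrisk.montecarlo import MonteCarloError


def point(v):
    return DistributionSpec("point", {"value": v})


def unif(lo, hi):
    return DistributionSpec("uniform", {"lower": lo, "upper": hi})


class TestRunMC:
    def test_point_mass_equals_direct_evaluation_bitwise(self):
        cfg = sr.MonteCarloConfig(n_iterations=100, seed=0)
        res = sr.run_mc(lambda a, b: a * b + 1.0, {"a": point(2.5), "b": point(4.0)}, cfg)
        assert np.all(res.draws == 2.5 * 4.0 + 1.0)
        assert res.mean == 2.5 * 4.0 + 1.0
        assert res.ci_high - res.ci_low == 0.0

    def test_seed_contract_identical_results(self):
        cfg = sr.MonteCarloConfig(n_iterations=1000, seed=42)
        inputs = {"x": unif(0, 1), "y": unif(1, 2)}
        r1 = sr.run_mc(lambda x, y: x + y, inputs, cfg)
        r2 = sr.run_mc(lambda x, y: x + y, inputs, cfg)
        assert np.array_equal(r1.draws, r2.draws)
        assert r1.to_dict() == r2.to_dict()

    def test_substreams_stable_under_added_variable(self):
        cfg = sr.MonteCarloConfig(n_iterations=500, seed=7)
        r1 = sr.run_mc(lambda x: x, {"x": unif(0, 1)}, cfg)
        r2 = sr.run_mc(lambda x, extra: x, {"x": unif(0, 1), "extra": unif(5, 6)}, cfg)
        assert np.array_equal(r1.draws, r2.draws)

    def test_percentile_ci_of_identity_on_uniform(self):
        cfg = sr.MonteCarloConfig(n_iterations=100_000, seed=1)
        res = sr.run_mc(lambda x: x, {"x": unif(0, 1)}, cfg)
        assert res.ci_low == pytest.approx(0.025, abs=0.005)
        assert res.ci_high == pytest.approx(0.975, abs=0.005)
        assert res.ci_low <= res.median <= res.ci_high

    def test_model_failure_reports_offending_inputs(self):
        cfg = sr.MonteCarloConfig(n_iterations=10, seed=0)
        with pytest.raises(MonteCarloError, match="x"):
            sr.run_mc(lambda x: np.log(x - 10.0), {"x": unif(0, 1)}, cfg)

    def test_doubling_iterations_keeps_mean_within_3_pooled_se(self):
        inputs = {"x": sr.fit_by_moments("lognormal", {"mean": 5.0, "cv": 40.0})}
        r1 = sr.run_mc(lambda x: x, inputs, sr.MonteCarloConfig(10_000, seed=3))
        r2 = sr.run_mc(lambda x: x, inputs, sr.MonteCarloConfig(20_000, seed=3))
        se = math.hypot(r1.draws.std() / 100, r2.draws.std() / math.sqrt(20_000))
        assert abs(r1.mean - r2.mean) < 3 * se


class TestClassProbabilities:
    def test_point_mass_all_in_one_class(self):
        cfg = sr.MonteCarloConfig(n_iterations=100, seed=0)
        res = sr.run_mc(lambda x: x, {"x": point(-2.0)}, cfg)
        probs = sr.class_probabilities(res, IGEO_SCHEME)
        assert probs["Uncontaminated"] == 1.0
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_lognormal_igeo_class_probability_vs_normal_cdf_oracle(self):
        # concentration model lognormal(mu=-1.9207, sigma=0.5452) against a
        # background of 0.047 mg/kg: the class (1, 2] probability has the
        # closed form Phi((ln 0.282 - mu)/sigma) - Phi((ln 0.141 - mu)/sigma)
        mu, sigma = -1.9207, 0.5452
        spec = DistributionSpec("lognormal", {"mu": mu, "sigma": sigma})
        cfg = sr.MonteCarloConfig(n_iterations=100_000, seed=11)
        res = sr.run_mc(lambda c: sr.igeo(c, 0.047), {"c": spec}, cfg)
        probs = sr.class_probabilities(res, IGEO_SCHEME)
        oracle = norm.cdf((math.log(0.282) - mu) / sigma) - norm.cdf(
            (math.log(0.141) - mu) / sigma
        )
        assert oracle == pytest.approx(0.413, abs=5e-4)
        assert probs["Moderately contaminated"] == pytest.approx(oracle, abs=0.02)

    def test_symmetric_split_at_median(self):
        cfg = sr.MonteCarloConfig(n_iterations=50_000, seed=5)
        res = sr.run_mc(lambda x: x, {"x": unif(-1, 1)}, cfg)
        scheme = sr.ClassificationScheme(breakpoints=(0.0,), labels=("lo", "hi"))
        probs = sr.class_probabilities(res, scheme)
        assert probs["lo"] == pytest.approx(0.5, abs=0.01)

    def test_exceedance_consistent_with_class_mass(self):
        cfg = sr.MonteCarloConfig(n_iterations=20_000, seed=9)
        res = sr.run_mc(lambda x: x, {"x": unif(-3, 7)}, cfg)
        probs = sr.class_probabilities(res, IGEO_SCHEME)
        # strictly-above mass at breakpoint 2 equals summed higher classes
        upper = sum(probs[lbl] for lbl in IGEO_SCHEME.labels[3:])
        assert sr.exceedance_probability(res, 2.0) == pytest.approx(upper, abs=1e-12)


class TestExceedance:
    def test_bounds(self):
        cfg = sr.MonteCarloConfig(n_iterations=100, seed=0)
        res = sr.run_mc(lambda x: x, {"x": unif(2, 3)}, cfg)
        assert sr.exceedance_probability(res, 1.0) == 1.0
        assert sr.exceedance_probability(res, 5.0) == 0.0

    def test_uniform_tail_fraction(self):
        cfg = sr.MonteCarloConfig(n_iterations=10_000, seed=2)
        res = sr.run_mc(lambda x: x, {"x": unif(0, 1)}, cfg)
        assert sr.exceedance_probability(res, 0.9) == pytest.approx(0.10, abs=0.01)


class TestSensitivity:
    def test_single_varying_input_is_plus_minus_100(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=1000)
        up = sr.sensitivity_contribution({"x": x}, 2 * x + 1)
        down = sr.sensitivity_contribution({"x": x}, -x)
        assert up["x"] == pytest.approx(100.0)
        assert down["x"] == pytest.approx(-100.0)

    def test_symmetric_sum_splits_50_50(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(size=10_000), rng.normal(size=10_000)
        contrib = sr.sensitivity_contribution({"x1": x1, "x2": x2}, x1 + x2)
        assert contrib["x1"] == pytest.approx(50.0, abs=3.0)
        assert contrib["x2"] == pytest.approx(50.0, abs=3.0)
        assert abs(contrib["x1"]) + abs(contrib["x2"]) == pytest.approx(100.0)

    def test_independent_input_near_zero(self):
        rng = np.random.default_rng(2)
        x1, x3 = rng.normal(size=10_000), rng.normal(size=10_000)
        contrib = sr.sensitivity_contribution({"x1": x1, "x3": x3}, x1)
        assert abs(contrib["x3"]) < 3.0

    def test_zero_variance_input_warns_and_zeroes(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        with pytest.warns(UserWarning, match="zero variance"):
            contrib = sr.sensitivity_contribution({"x": x, "c": np.full(100, 2.0)}, x)
        assert contrib["c"] == 0.0

    def test_negative_body_weight_correlation_in_health_model(self, profile):
        conc = {m: p.mean for m, p in profile.metals.items()}
        mc = sr.MonteCarloConfig(n_iterations=20_000, seed=6)
        res = sr.hazard_index_mc(conc, sr.default_profiles()["child"], "ingestion", mc)
        contrib = sr.sensitivity_contribution(res.input_draws, res.draws)
        assert contrib["bw"] < -50.0  # dose is inversely proportional to BW


class TestErOracle:
    def test_mc_mean_er_matches_analytic_lognormal_oracle(self):
        # for lognormal concentrations, E[tr*cn/C] = tr*cn*(1/mean)*(1+cv^2)
        mean, cv, cn, tr = 31.98, 18.59, 23.30, 5.0
        spec = sr.fit_by_moments("lognormal", {"mean": mean, "cv": cv})
        cfg = sr.MonteCarloConfig(n_iterations=100_000, seed=13)
        res = sr.run_mc(
            lambda c: sr.single_metal_risk(sr.contamination_factor(c, cn), tr),
            {"c": spec},
            cfg,
        )
        oracle = tr * cn / mean * (1 + (cv / 100) ** 2)
        se = res.draws.std() / math.sqrt(res.draws.size)
        assert abs(res.mean - oracle) < 3 * se
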