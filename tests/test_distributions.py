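"""Moment fitting, Anderson–Darling goodness of fit, family selection,
seeded sampling."""

import math

import numpy as np
import pytest

import sedrisk as sr
from sedrisk.distributions import DistributionSpec, FitError


def uniform(lo, hi):
    return DistributionSpec("uniform", {"lower": lo, "upper": hi})


class TestFitByMoments:
    def test_uniform_midpoint_mean(self):
        spec = sr.fit_by_moments("uniform", {"min": 0.0, "max": 2.0, "mean": 1.0, "sd": 0.5})
        assert spec.mean() == pytest.approx(1.0)

    def test_lognormal_closed_form(self):
        # sigma^2 = ln(1 + cv^2), mu = ln(mean) - sigma^2/2
        spec = sr.fit_by_moments("lognormal", {"mean": 0.17, "cv": 55.07})
        sigma2 = math.log1p(0.5507**2)
        assert spec.params["sigma"] == pytest.approx(math.sqrt(sigma2), abs=1e-9)
        assert spec.params["mu"] == pytest.approx(math.log(0.17) - sigma2 / 2, abs=1e-9)

    def test_triangular_mode_rule(self):
        spec = sr.fit_by_moments(
            "triangular", {"min": 57.00, "max": 85.10, "mean": 73.71, "sd": 8.98}
        )
        assert spec.params["mode"] == pytest.approx(79.03, abs=1e-9)

    def test_triangular_mode_clamped_into_support(self):
        spec = sr.fit_by_moments("triangular", {"min": 0.0, "max": 1.0, "mean": 0.9, "sd": 0.1})
        assert spec.params["lower"] <= spec.params["mode"] <= spec.params["upper"]

    @pytest.mark.parametrize(
        "family,stats",
        [
            ("point", {"mean": 3.7, "sd": 0.0}),
            ("normal", {"mean": 10.0, "sd": 2.0}),
            ("lognormal", {"mean": 0.17, "cv": 55.07}),
            ("weibull", {"mean": 31.98, "cv": 18.59}),
            ("uniform", {"min": 21.9, "max": 38.3, "mean": 30.1, "sd": 4.7}),
            ("beta_scaled", {"min": 0.17, "max": 0.77, "mean": 0.46, "cv": 34.43}),
        ],
    )
    def test_fitted_mean_matches_request(self, family, stats):
        spec = sr.fit_by_moments(family, stats)
        if family == "uniform":  # mean is implied by the bounds, not requested
            assert spec.mean() == pytest.approx((21.9 + 38.3) / 2, abs=1e-9)
        else:
            assert spec.mean() == pytest.approx(stats["mean"], abs=1e-9)

    @pytest.mark.parametrize(
        "family,stats",
        [
            ("normal", {"mean": 10.0, "sd": 2.0}),
            ("lognormal", {"mean": 0.17, "cv": 55.07}),
            ("weibull", {"mean": 31.98, "cv": 18.59}),
            ("beta_scaled", {"min": 0.17, "max": 0.77, "mean": 0.46, "cv": 34.43}),
        ],
    )
    def test_fitted_sd_matches_request(self, family, stats):
        spec = sr.fit_by_moments(family, stats)
        sd = stats.get("sd", stats["mean"] * stats.get("cv", 0.0) / 100.0)
        assert spec.sd() == pytest.approx(sd, rel=1e-9)

    def test_beta_infeasible_variance(self):
        with pytest.raises(FitError, match="variance"):
            sr.fit_by_moments("beta_scaled", {"min": 0.0, "max": 1.0, "mean": 0.5, "sd": 0.6})

    def test_nonpositive_cv_rejected(self):
        with pytest.raises(FitError):
            sr.fit_by_moments("lognormal", {"mean": 1.0, "cv": -5.0})

    def test_discrete_uniform_fallback_triangular(self):
        stats = {"min": 567.0, "max": 1850.0, "mean": 1112.95, "cv": 33.34}
        spec = sr.fit_by_moments("discrete_uniform", stats)
        assert spec.family == "triangular"
        expected_mode = 3 * 1112.95 - 567.0 - 1850.0
        assert spec.params["mode"] == pytest.approx(expected_mode)

    def test_discrete_uniform_fallback_lognormal(self):
        stats = {"min": 567.0, "max": 1850.0, "mean": 1112.95, "cv": 33.34}
        spec = sr.fit_by_moments("discrete_uniform", stats, discrete_fallback="lognormal")
        assert spec.family == "lognormal"
        assert spec.mean() == pytest.approx(1112.95, abs=1e-9)


class TestAndersonDarling:
    def test_worked_examples_exact_to_4dp(self):
        samples = [0.25, 0.50, 0.75]
        assert sr.anderson_darling(samples, uniform(0, 1)) == pytest.approx(0.2694, abs=5e-5)
        assert sr.anderson_darling(samples, uniform(0, 2)) == pytest.approx(1.3810, abs=1e-4)

    def test_mismatched_support_scores_worse(self):
        samples = [0.25, 0.50, 0.75]
        assert sr.anderson_darling(samples, uniform(0, 2)) > sr.anderson_darling(
            samples, uniform(0, 1)
        )

    def test_matched_quantiles_beat_location_shifts(self):
        spec = DistributionSpec("normal", {"mean": 0.0, "sd": 1.0})
        n = 25
        samples = spec.frozen().ppf((np.arange(1, n + 1) - 0.5) / n)
        matched = sr.anderson_darling(samples, spec)
        for shift in (-0.5, -0.1, 0.1, 0.5):
            shifted = DistributionSpec("normal", {"mean": shift, "sd": 1.0})
            assert matched < sr.anderson_darling(samples, shifted)

    @pytest.mark.parametrize("scale,shift", [(2.0, 0.0), (1.0, 3.0), (0.25, -1.5)])
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(42)
        samples = rng.normal(5.0, 2.0, size=50)
        spec = DistributionSpec("normal", {"mean": 5.0, "sd": 2.0})
        base = sr.anderson_darling(samples, spec)
        moved = DistributionSpec(
            "normal", {"mean": 5.0 * scale + shift, "sd": 2.0 * scale}
        )
        assert sr.anderson_darling(samples * scale + shift, moved) == pytest.approx(
            base, abs=1e-9
        )

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            sr.anderson_darling([0.5, 0.6], uniform(0, 1))


class TestSelectFamily:
    def test_single_candidate_selected(self):
        x = sr.sample(uniform(0, 1), 100, 1)
        ranked = sr.select_family(x, ["normal"])
        assert ranked[0][0] == "normal"

    def test_uniform_beats_normal_on_uniform_draws(self):
        x = sr.sample(uniform(0, 1), 500, 7)
        ranked = sr.select_family(x, ["uniform", "normal"])
        assert ranked[0][0] == "uniform"
        assert ranked[0][2] < ranked[1][2]

    def test_exact_ties_preserve_candidate_order(self):
        x = sr.sample(uniform(0, 1), 50, 3)
        ranked = sr.select_family(x, ["uniform", "uniform"])
        assert [fam for fam, _, _ in ranked] == ["uniform", "uniform"]
        assert ranked[0][2] == ranked[1][2]

    def test_all_candidates_fail_reports_reasons(self):
        x = np.array([-1.0, -2.0, -3.0, -4.0])
        with pytest.raises(FitError, match="lognormal"):
            sr.select_family(x, ["lognormal", "weibull"])

    def test_empty_candidates(self):
        with pytest.raises(ValueError):
            sr.select_family([1.0, 2.0, 3.0], [])


class TestSampling:
    def test_point_mass_constant(self):
        spec = DistributionSpec("point", {"value": 3.7})
        assert np.array_equal(sr.sample(spec, 5, 0), np.full(5, 3.7))

    def test_seed_determinism_bitwise(self):
        spec = sr.fit_by_moments("weibull", {"mean": 31.98, "cv": 18.59})
        a = sr.sample(spec, 1000, 99)
        b = sr.sample(spec, 1000, 99)
        assert np.array_equal(a, b)

    def test_draws_within_support(self):
        spec = DistributionSpec("triangular", {"lower": 1.0, "mode": 2.0, "upper": 3.0})
        x = sr.sample(spec, 5000, 11)
        assert x.min() >= 1.0 and x.max() <= 3.0

    def test_discrete_uniform_draws_from_value_list(self):
        spec = DistributionSpec("discrete_uniform", {"values": [1.0, 2.0, 5.0]})
        x = sr.sample(spec, 300, 13)
        assert set(np.unique(x)) <= {1.0, 2.0, 5.0}

    def test_lognormal_sample_mean_within_3se(self):
        spec = sr.fit_by_moments("lognormal", {"mean": 0.17, "cv": 55.07})
        n = 100_000
        x = sr.sample(spec, n, 5)
        se = spec.sd() / math.sqrt(n)
        assert abs(x.mean() - 0.17) < 3 * se

    def test_sample_summarize_fit_roundtrip_recovers_lognormal(self):
        spec = sr.fit_by_moments("lognormal", {"mean": 12.43, "cv": 38.82})
        x = sr.sample(spec, 100_000, 21)
        refit = sr.fit_by_moments(
            "lognormal", {"mean": float(x.mean()), "sd": float(x.std(ddof=1))}
        )
        assert refit.params["mu"] == pytest.approx(spec.params["mu"], rel=0.05)
        assert refit.params["sigma"] == pytest.approx(spec.params["sigma"], rel=0.05)


class TestSpecSerialization:
    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec("point", {"value": 1.5}),
            DistributionSpec("lognormal", {"mu": -1.9, "sigma": 0.51}),
            DistributionSpec("discrete_uniform", {"values": [1.0, 2.0]}),
            DistributionSpec("beta_scaled", {"alpha": 2.0, "beta": 3.0, "lower": 0.1, "upper": 0.8}),
        ],
    )
    def test_dict_roundtrip(self, spec):
        back = DistributionSpec.from_dict(spec.to_dict())
        assert back.family == spec.family
        assert back.mean() == pytest.approx(spec.mean())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("triangular", {"lower": 2.0, "mode": 1.0, "upper": 3.0})
        with pytest.raises(ValueError):
            DistributionSpec("lognormal", {"mu": 0.0, "sigma": -1.0})
        with pytest.raises(ValueError):
            DistributionSpec("nopesuchfamily", {})
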