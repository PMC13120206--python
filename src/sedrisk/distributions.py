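"""Parametric distributions: moment fitting, goodness of fit, seeded sampling.

A single :class:`DistributionSpec` type represents both sediment-concentration
models and human exposure-parameter distributions.  Fitting is by moment
matching (closed forms where they exist, a one-dimensional root solve for the
Weibull shape); model comparison uses the Anderson–Darling statistic evaluated
against the *fitted* cumulative distribution function, used comparatively
(no p-values).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "CONTINUOUS_FAMILIES",
    "FAMILIES",
    "DistributionSpec",
    "FitError",
    "anderson_darling",
    "fit_by_moments",
    "sample",
    "select_family",
    "substream",
]

FAMILIES = (
    "point",
    "normal",
    "lognormal",
    "beta_scaled",
    "weibull",
    "triangular",
    "uniform",
    "discrete_uniform",
)

#: families with a continuous CDF (usable in the Anderson–Darling statistic)
CONTINUOUS_FAMILIES = (
    "normal",
    "lognormal",
    "beta_scaled",
    "weibull",
    "triangular",
    "uniform",
)

# canonical parameter names per family, in serialization order
_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "point": ("value",),
    "normal": ("mean", "sd"),
    "lognormal": ("mu", "sigma"),
    "beta_scaled": ("alpha", "beta", "lower", "upper"),
    "weibull": ("shape", "scale"),
    "triangular": ("lower", "mode", "upper"),
    "uniform": ("lower", "upper"),
    "discrete_uniform": ("values",),
}

# probability-integral values are clipped this far away from {0, 1}
_AD_CLIP = 1e-12


class FitError(ValueError):
    """Raised when requested moments are infeasible for a family."""


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric distribution (family tag + parameters).

    Parameters are held in a plain dict keyed by the family's canonical
    parameter names; see module source for the naming table.  Instances are
    immutable and serialize to/from plain dicts (and hence YAML/JSON).
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        names = _PARAM_NAMES[self.family]
        missing = [n for n in names if n not in self.params]
        if missing:
            raise ValueError(f"{self.family}: missing parameter(s) {missing}")
        p = self.params
        if self.family == "normal" and p["sd"] < 0:
            raise ValueError("normal: sd must be >= 0")
        if self.family == "lognormal" and p["sigma"] <= 0:
            raise ValueError("lognormal: sigma must be > 0")
        if self.family == "beta_scaled":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise ValueError("beta_scaled: shapes must be > 0")
            if not p["lower"] < p["upper"]:
                raise ValueError("beta_scaled: lower must be < upper")
        if self.family == "weibull" and (p["shape"] <= 0 or p["scale"] <= 0):
            raise ValueError("weibull: shape and scale must be > 0")
        if self.family == "triangular":
            if not p["lower"] <= p["mode"] <= p["upper"]:
                raise ValueError("triangular: require lower <= mode <= upper")
            if not p["lower"] < p["upper"]:
                raise ValueError("triangular: lower must be < upper")
        if self.family == "uniform" and not p["lower"] < p["upper"]:
            raise ValueError("uniform: lower must be < upper")
        if self.family == "discrete_uniform" and len(p["values"]) == 0:
            raise ValueError("discrete_uniform: value list must be non-empty")

    # -- scipy bridge ------------------------------------------------------

    def frozen(self):
        """Return the equivalent frozen scipy.stats distribution.

        Raises :class:`ValueError` for the point and discrete_uniform
        families, which have no continuous scipy counterpart here.
        """
        p = self.params
        if self.family == "normal":
            return stats.norm(loc=p["mean"], scale=p["sd"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        if self.family == "beta_scaled":
            return stats.beta(
                p["alpha"], p["beta"], loc=p["lower"], scale=p["upper"] - p["lower"]
            )
        if self.family == "weibull":
            return stats.weibull_min(p["shape"], scale=p["scale"])
        if self.family == "triangular":
            width = p["upper"] - p["lower"]
            return stats.triang(
                c=(p["mode"] - p["lower"]) / width, loc=p["lower"], scale=width
            )
        if self.family == "uniform":
            return stats.uniform(loc=p["lower"], scale=p["upper"] - p["lower"])
        raise ValueError(f"{self.family} has no continuous scipy form")

    # -- analytic properties ----------------------------------------------

    def mean(self) -> float:
        p = self.params
        if self.family == "point":
            return float(p["value"])
        if self.family == "discrete_uniform":
            return float(np.mean(p["values"]))
        return float(self.frozen().mean())

    def sd(self) -> float:
        p = self.params
        if self.family == "point":
            return 0.0
        if self.family == "discrete_uniform":
            return float(np.std(p["values"]))
        return float(self.frozen().std())

    def support(self) -> tuple[float, float]:
        p = self.params
        if self.family == "point":
            return (p["value"], p["value"])
        if self.family == "discrete_uniform":
            return (float(min(p["values"])), float(max(p["values"])))
        lo, hi = self.frozen().support()
        return (float(lo), float(hi))

    def cdf(self, x):
        """Continuous CDF; raises for point/discrete_uniform families."""
        if self.family not in CONTINUOUS_FAMILIES:
            raise ValueError(
                f"{self.family} has no continuous CDF (needed for goodness of fit)"
            )
        return self.frozen().cdf(np.asarray(x, dtype=float))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` variates using the supplied generator."""
        if n < 1:
            raise ValueError("n must be >= 1")
        p = self.params
        if self.family == "point":
            return np.full(n, float(p["value"]))
        if self.family == "discrete_uniform":
            return rng.choice(np.asarray(p["values"], dtype=float), size=n)
        return np.asarray(self.frozen().rvs(size=n, random_state=rng), dtype=float)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        lo, hi = self.support()
        return {
            "family": self.family,
            "params": {
                k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else float(v))
                for k, v in self.params.items()
            },
            "support": [lo if math.isfinite(lo) else None, hi if math.isfinite(hi) else None],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        return cls(family=d["family"], params=dict(d["params"]))


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent random substream for a named variable.

    The stream is derived from the root seed and a stable hash of the name,
    so adding or removing other variables never perturbs this one's draws.
    """
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def sample(spec: DistributionSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` variates reproducibly: same (spec, n, seed) -> same output."""
    return spec.rvs(n, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# moment fitting
# ---------------------------------------------------------------------------


def _extract_moments(stats_entry) -> tuple[float, float, float, float]:
    """Pull (min, max, mean, sd) out of a mapping / namespace / pandas row.

    ``sd`` may be given directly or derived from ``cv`` (percent of mean).
    """

    def get(key):
        if isinstance(stats_entry, Mapping):
            return stats_entry.get(key)
        return getattr(stats_entry, key, None)

    mn, mx, mean = get("min"), get("max"), get("mean")
    sd, cv = get("sd"), get("cv")
    if mean is None:
        raise FitError("moment fitting requires a mean")
    if sd is None:
        if cv is None:
            raise FitError("moment fitting requires sd or cv")
        if cv < 0:
            raise FitError("cv must be >= 0")
        sd = float(mean) * float(cv) / 100.0
    return (
        float(mn) if mn is not None else math.nan,
        float(mx) if mx is not None else math.nan,
        float(mean),
        float(sd),
    )


def _weibull_shape_from_cv(cv: float) -> float:
    """Solve Gamma(1+2/k)/Gamma(1+1/k)^2 - 1 = cv^2 for the shape k."""

    def f(k):
        g1 = special.gammaln(1 + 1 / k)
        g2 = special.gammaln(1 + 2 / k)
        return math.expm1(g2 - 2 * g1) - cv * cv

    return optimize.brentq(f, 0.05, 200.0, xtol=1e-12, rtol=1e-14)


def fit_by_moments(
    family: str,
    stats_entry,
    *,
    discrete_fallback: str = "triangular",
) -> DistributionSpec:
    """Fit a family to summary moments (closed-form moment matching).

    Rules: lognormal uses sigma^2 = ln(1 + cv^2), mu = ln(mean) - sigma^2/2;
    uniform spans [min, max]; triangular takes mode = 3*mean - min - max,
    clamped into [min, max]; beta is fitted on the rescaled [min, max]
    interval; the Weibull shape is solved numerically from the cv and the
    scale from the mean.  The discrete_uniform family is not recoverable from
    moments, so it falls back to the rule named by ``discrete_fallback``
    ("triangular", the default, or "lognormal").
    """
    if family not in FAMILIES:
        raise FitError(f"unknown family {family!r}")
    mn, mx, mean, sd = _extract_moments(stats_entry)

    if family == "point":
        return DistributionSpec("point", {"value": mean})
    if family == "normal":
        return DistributionSpec("normal", {"mean": mean, "sd": sd})
    if family == "uniform":
        if not (math.isfinite(mn) and math.isfinite(mx)):
            raise FitError("uniform fit requires min and max")
        return DistributionSpec("uniform", {"lower": mn, "upper": mx})
    if family == "lognormal":
        if mean <= 0:
            raise FitError("lognormal fit requires mean > 0")
        if sd <= 0:
            raise FitError("lognormal fit requires cv > 0")
        cv = sd / mean
        sigma2 = math.log1p(cv * cv)
        return DistributionSpec(
            "lognormal",
            {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)},
        )
    if family == "weibull":
        if mean <= 0 or sd <= 0:
            raise FitError("weibull fit requires mean > 0 and cv > 0")
        shape = _weibull_shape_from_cv(sd / mean)
        scale = mean / math.exp(special.gammaln(1 + 1 / shape))
        return DistributionSpec("weibull", {"shape": shape, "scale": scale})
    if family == "triangular" or (
        family == "discrete_uniform" and discrete_fallback == "triangular"
    ):
        if not (math.isfinite(mn) and math.isfinite(mx)):
            raise FitError("triangular fit requires min and max")
        mode = 3.0 * mean - mn - mx
        mode = min(max(mode, mn), mx)
        return DistributionSpec("triangular", {"lower": mn, "mode": mode, "upper": mx})
    if family == "discrete_uniform":
        if discrete_fallback != "lognormal":
            raise FitError(f"unknown discrete_fallback {discrete_fallback!r}")
        return fit_by_moments("lognormal", {"min": mn, "max": mx, "mean": mean, "sd": sd})
    if family == "beta_scaled":
        if not (math.isfinite(mn) and math.isfinite(mx)) or not mn < mx:
            raise FitError("beta fit requires min < max")
        width = mx - mn
        m = (mean - mn) / width
        v = (sd / width) ** 2
        if not 0.0 < m < 1.0:
            raise FitError("beta fit: mean outside (min, max)")
        if v <= 0 or v >= m * (1.0 - m):
            raise FitError(
                "beta fit: variance infeasible for the [min, max] support; "
                "consider the triangular or uniform family instead"
            )
        nu = m * (1.0 - m) / v - 1.0
        return DistributionSpec(
            "beta_scaled",
            {"alpha": m * nu, "beta": (1.0 - m) * nu, "lower": mn, "upper": mx},
        )
    raise FitError(f"no moment rule for family {family!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# goodness of fit / family selection
# ---------------------------------------------------------------------------


def anderson_darling(samples: Iterable[float], spec: DistributionSpec) -> float:
    """Anderson–Darling statistic A^2 of samples against a fixed spec.

    A^2 = -n - (1/n) * sum_{i=1..n} (2i-1) * [ln F(x_(i)) + ln(1 - F(x_(n+1-i)))]
    with probability-integral values clipped to [1e-12, 1 - 1e-12].  Used
    comparatively across candidate specs; no reference to critical values.
    """
    x = np.sort(np.asarray(list(samples), dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("Anderson–Darling statistic requires n >= 3")
    f = np.clip(spec.cdf(x), _AD_CLIP, 1.0 - _AD_CLIP)
    i = np.arange(1, n + 1)
    terms = (2 * i - 1) * (np.log(f) + np.log1p(-f[::-1]))
    if not np.all(np.isfinite(terms)):
        bad = int(np.flatnonzero(~np.isfinite(terms))[0])
        raise ValueError(f"degenerate probability integral at sample x={x[bad]!r}")
    return float(-n - terms.sum() / n)


def select_family(
    samples: Iterable[float],
    candidates: Sequence[str],
) -> list[tuple[str, DistributionSpec, float]]:
    """Rank candidate families by Anderson–Darling fit to the samples.

    Each candidate is moment-fitted from the samples' own summary (n-1 sd),
    then scored; the result is sorted ascending by A^2 with ties broken by
    the candidate-list order (stable sort).  The head of the list is the
    selected family.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    x = np.asarray(list(samples), dtype=float)
    summary = {
        "min": float(x.min()),
        "max": float(x.max()),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
    }
    ranked: list[tuple[str, DistributionSpec, float]] = []
    failures: dict[str, str] = {}
    for fam in candidates:
        try:
            spec = fit_by_moments(fam, summary)
            if spec.family not in CONTINUOUS_FAMILIES:
                raise FitError(f"{fam}: no continuous CDF for goodness of fit")
            ranked.append((fam, spec, anderson_darling(x, spec)))
        except (FitError, ValueError) as exc:
            failures[fam] = str(exc)
    if not ranked:
        detail = "; ".join(f"{k}: {v}" for k, v in failures.items())
        raise FitError(f"no candidate family could be fitted ({detail})")
    ranked.sort(key=lambda item: item[2])  # stable: ties keep list order
    return ranked
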