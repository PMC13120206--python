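"""USEPA-style human health risk model: exposure doses, hazard quotients
and indices, carcinogenic risk, for three population groups via the oral
ingestion and dermal contact pathways.

Average daily doses (mg/(kg*d)):

    CDD_ing  = ck * IR_ing * ED * EF * CF / (BW * AT)
    CDD_derm = ck * SA * AF * ABS * ED * EF * CF / (BW * AT)

with the skin area SA given in m^2 and the adherence factor AF in
mg/(cm^2*d), so SA is converted to cm^2 (x 1e4) before the product; the
unit conversion factor CF is 1e-6 kg/mg.  Non-carcinogenic averaging time
is AT = 365*ED days (ED cancels analytically); carcinogenic averaging time
is AT = 365*70 days, so carcinogenic doses scale as ED/70.

Hazard quotient HQ = CDD/RfD per metal; hazard index HI sums the nine HQs
and flags HI > 1 as a potential non-carcinogenic risk.  Carcinogenic risk
CR = CDD_carc * SF exists only for metal/route pairs with a published slope
factor; TCR sums the available CRs and is graded negligible (< 1e-6),
acceptable ([1e-6, 1e-4)) or unacceptable (>= 1e-4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .distributions import DistributionSpec, fit_by_moments
from .montecarlo import MCResult, MonteCarloConfig, run_mc
from .references import ToxicologyTable, default_toxicology_table
from .samples import METALS

__all__ = [
    "GROUPS",
    "ROUTES",
    "SA_CM2_PER_M2",
    "ExposureProfile",
    "carcinogenic_risk",
    "cdd_dermal",
    "cdd_ingestion",
    "classify_tcr",
    "default_profiles",
    "hazard_index",
    "hazard_index_mc",
    "hazard_quotient",
    "total_carcinogenic_risk_mc",
]

logger = logging.getLogger(__name__)

GROUPS = ("adult_male", "adult_female", "child")
ROUTES = ("ingestion", "dermal")

#: m^2 -> cm^2 bridge between the skin-area and adherence-factor units
SA_CM2_PER_M2 = 1.0e4

#: carcinogenic averaging time, days (lifetime 70 years)
AT_CARCINOGENIC_DAYS = 365.0 * 70.0


def _point(value: float) -> DistributionSpec:
    return DistributionSpec("point", {"value": value})


def _triangular(lower: float, mode: float, upper: float) -> DistributionSpec:
    return DistributionSpec("triangular", {"lower": lower, "mode": mode, "upper": upper})


def _lognormal_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    # arithmetic mean/sd bridged to (mu, sigma) by the moment-match rule;
    # heavy-tailed cases (sd > mean) are valid and left untruncated above
    return fit_by_moments("lognormal", {"mean": mean, "sd": sd})


@dataclass(frozen=True)
class ExposureProfile:
    """One population group's exposure-parameter distributions.

    Units: ir_ing mg/d; ed years; ef_freq d/year (exposure frequency —
    named ef_freq to avoid any collision with the enrichment factor);
    bw kg; sa m^2; af mg/(cm^2*d); cf_unit kg/mg.
    """

    group: str
    ir_ing: DistributionSpec
    ed: DistributionSpec
    ef_freq: DistributionSpec
    bw: DistributionSpec
    sa: DistributionSpec
    af: DistributionSpec
    cf_unit: float = 1.0e-6

    def ed_years(self) -> float:
        """Exposure duration as a point value (all default profiles use one)."""
        if self.ed.family != "point":
            raise ValueError("exposure duration must be a point value")
        return float(self.ed.params["value"])


def default_profiles() -> dict[str, ExposureProfile]:
    """Exposure-parameter distributions for the three population groups.

    Adults: ingestion rate 114 mg/d, duration 70 a, body weight lognormal
    (males 67.55 +/- 8.72 kg, females 57.59 +/- 8.03 kg).  Children:
    ingestion rate 200 mg/d, duration 18 a, body weight triangular
    29.30 (5.20-56.80) kg.  Exposure frequency triangular 345 (180-365) d/a
    for all groups; skin adherence lognormal (adults 0.49 +/- 0.54, children
    0.65 +/- 1.2 mg/(cm^2*d)); skin areas triangular per group, m^2.
    """
    ef = _triangular(180.0, 345.0, 365.0)
    return {
        "adult_male": ExposureProfile(
            group="adult_male",
            ir_ing=_point(114.0),
            ed=_point(70.0),
            ef_freq=ef,
            bw=_lognormal_from_mean_sd(67.55, 8.72),
            sa=_triangular(0.085, 0.169, 0.422),
            af=_lognormal_from_mean_sd(0.49, 0.54),
        ),
        "adult_female": ExposureProfile(
            group="adult_female",
            ir_ing=_point(114.0),
            ed=_point(70.0),
            ef_freq=ef,
            bw=_lognormal_from_mean_sd(57.59, 8.03),
            sa=_triangular(0.076, 0.153, 0.382),
            af=_lognormal_from_mean_sd(0.49, 0.54),
        ),
        "child": ExposureProfile(
            group="child",
            ir_ing=_point(200.0),
            ed=_point(18.0),
            ef_freq=ef,
            bw=_triangular(5.20, 29.30, 56.80),
            sa=_triangular(0.043, 0.086, 0.216),
            af=_lognormal_from_mean_sd(0.65, 1.2),
        ),
    }


# ---------------------------------------------------------------------------
# dose equations
# ---------------------------------------------------------------------------


def _require_positive(**values) -> None:
    for name, v in values.items():
        if np.any(~(np.asarray(v, dtype=float) > 0)):
            raise ValueError(f"{name} must be strictly positive")


def cdd_ingestion(ck, ir_ing, ed, ef_freq, bw, at, cf=1.0e-6):
    """Average daily dose via ingestion, mg/(kg*d). ``at`` in days."""
    _require_positive(ir_ing=ir_ing, ed=ed, ef_freq=ef_freq, bw=bw, at=at, cf=cf)
    ck = np.asarray(ck, dtype=float)
    if np.any(ck < 0):
        raise ValueError("ck must be non-negative")
    return ck * np.asarray(ir_ing, float) * np.asarray(ed, float) * np.asarray(
        ef_freq, float
    ) * cf / (np.asarray(bw, float) * np.asarray(at, float))


def cdd_dermal(ck, sa, af, abs_frac, ed, ef_freq, bw, at, cf=1.0e-6):
    """Average daily dose via dermal contact, mg/(kg*d).

    ``sa`` is in m^2 and converted to cm^2 internally to match ``af`` in
    mg/(cm^2*d); ``abs_frac`` may be 0 (no absorption -> zero dose).
    """
    _require_positive(sa=sa, af=af, ed=ed, ef_freq=ef_freq, bw=bw, at=at, cf=cf)
    ck = np.asarray(ck, dtype=float)
    if np.any(ck < 0):
        raise ValueError("ck must be non-negative")
    if np.any(np.asarray(abs_frac, float) < 0):
        raise ValueError("abs_frac must be non-negative")
    sa_cm2 = np.asarray(sa, float) * SA_CM2_PER_M2
    return ck * sa_cm2 * np.asarray(af, float) * np.asarray(abs_frac, float) * np.asarray(
        ed, float
    ) * np.asarray(ef_freq, float) * cf / (np.asarray(bw, float) * np.asarray(at, float))


def hazard_quotient(cdd, rfd):
    """HQ = dose over reference dose (dimensionless)."""
    _require_positive(rfd=rfd)
    return np.asarray(cdd, dtype=float) / np.asarray(rfd, dtype=float)


def hazard_index(hqs: Mapping[str, float]) -> tuple[float, str]:
    """HI = sum of the nine per-metal HQs; flag 'potential' iff HI > 1."""
    missing = [m for m in METALS if m not in hqs]
    if missing:
        raise ValueError(f"missing hazard quotient(s) for: {', '.join(missing)}")
    hi = float(sum(float(hqs[m]) for m in METALS))
    return hi, ("potential" if hi > 1.0 else "negligible")


def carcinogenic_risk(cdd_carc, sf: Optional[float]):
    """CR = carcinogenic dose x slope factor, or None without a published SF."""
    if sf is None:
        return None
    _require_positive(sf=sf)
    return np.asarray(cdd_carc, dtype=float) * sf


def classify_tcr(tcr: float) -> str:
    """Grade a total carcinogenic risk value.

    negligible < 1e-6 <= acceptable < 1e-4 <= unacceptable (the exact 1e-4
    boundary is classed unacceptable).
    """
    if tcr < 0:
        raise ValueError("tcr must be >= 0")
    if tcr < 1e-6:
        return "negligible"
    if tcr < 1e-4:
        return "acceptable"
    return "unacceptable"


# ---------------------------------------------------------------------------
# Monte Carlo propagation of the dose model
# ---------------------------------------------------------------------------


def _hi_factor(conc: Mapping[str, float], tox: ToxicologyTable, route: str) -> float:
    """sum_k ck * (ABS_k if dermal) / RfD_k — the concentration-toxicity part
    of HI, which factors out of the exposure-parameter randomness."""
    total = 0.0
    for metal in METALS:
        ck = float(conc[metal])
        if ck < 0:
            raise ValueError(f"negative concentration for {metal}")
        if route == "ingestion":
            total += ck / tox.rfd(metal, "ingestion")
        else:
            total += ck * tox.abs_dermal[metal] / tox.rfd(metal, "dermal")
    return total


def hazard_index_mc(
    conc: Mapping[str, float],
    profile: ExposureProfile,
    route: str,
    config: MonteCarloConfig,
    toxicology: Optional[ToxicologyTable] = None,
) -> MCResult:
    """Monte Carlo draws of the hazard index for one group and route.

    ``conc`` maps each metal to a (fixed) sediment concentration in mg/kg;
    exposure parameters are drawn from the profile's distributions.  The
    non-carcinogenic averaging time 365*ED cancels the exposure duration.
    """
    if route not in ROUTES:
        raise ValueError(f"unknown route {route!r}")
    tox = toxicology if toxicology is not None else default_toxicology_table()
    factor = _hi_factor(conc, tox, route)
    cf = profile.cf_unit
    if route == "ingestion":
        inputs = {"ir_ing": profile.ir_ing, "ef_freq": profile.ef_freq, "bw": profile.bw}

        def model(ir_ing, ef_freq, bw):
            # AT = 365*ED cancels ED; per-day dose factor remains
            return factor * ir_ing * ef_freq * cf / (bw * 365.0)

    else:
        inputs = {
            "sa": profile.sa,
            "af": profile.af,
            "ef_freq": profile.ef_freq,
            "bw": profile.bw,
        }

        def model(sa, af, ef_freq, bw):
            return factor * sa * SA_CM2_PER_M2 * af * ef_freq * cf / (bw * 365.0)

    return run_mc(model, inputs, config)


def total_carcinogenic_risk_mc(
    conc: Mapping[str, float],
    profile: ExposureProfile,
    route: str,
    config: MonteCarloConfig,
    toxicology: Optional[ToxicologyTable] = None,
) -> Optional[MCResult]:
    """Monte Carlo draws of TCR (sum of CR over metals with a slope factor).

    Uses the carcinogenic averaging time 365*70 days, so the dose scales as
    ED/70.  Returns None when no metal has a slope factor on the route.
    """
    if route not in ROUTES:
        raise ValueError(f"unknown route {route!r}")
    tox = toxicology if toxicology is not None else default_toxicology_table()
    ed = profile.ed_years()
    cf = profile.cf_unit
    factor = 0.0
    for metal in METALS:
        sf = tox.sf(metal, route)
        if sf is None:
            logger.info("no %s slope factor for %s: CR skipped", route, metal)
            continue
        ck = float(conc[metal])
        if route == "ingestion":
            factor += ck * sf
        else:
            factor += ck * tox.abs_dermal[metal] * sf
    if factor == 0.0:
        return None

    if route == "ingestion":
        inputs = {"ir_ing": profile.ir_ing, "ef_freq": profile.ef_freq, "bw": profile.bw}

        def model(ir_ing, ef_freq, bw):
            return factor * ir_ing * ed * ef_freq * cf / (bw * AT_CARCINOGENIC_DAYS)

    else:
        inputs = {
            "sa": profile.sa,
            "af": profile.af,
            "ef_freq": profile.ef_freq,
            "bw": profile.bw,
        }

        def model(sa, af, ef_freq, bw):
            return (
                factor
                * sa
                * SA_CM2_PER_M2
                * af
                * ed
                * ef_freq
                * cf
                / (bw * AT_CARCINOGENIC_DAYS)
            )

    return run_mc(model, inputs, config)
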