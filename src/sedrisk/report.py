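"""End-to-end pipeline: simulate/load -> fit -> indices -> ecological risk
-> health risk -> Monte Carlo summaries -> tidy report bundle.

Every stage writes plain CSV/JSON into the output directory; a run log
records the seed, package version and Er mode.  A stage failure aborts the
run, removes any partial outputs, and names the failing stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .distributions import CONTINUOUS_FAMILIES, DistributionSpec, select_family, substream
from .health import (
    GROUPS,
    ROUTES,
    classify_tcr,
    default_profiles,
    hazard_index_mc,
    total_carcinogenic_risk_mc,
)
from .indices import (
    EF_SCHEME,
    IGEO_SCHEME,
    RI_SCHEME,
    compute_index_table,
    contamination_factor,
    igeo,
    single_metal_risk,
)
from .montecarlo import (
    MCResult,
    MonteCarloConfig,
    class_probabilities,
    exceedance_probability,
    sensitivity_contribution,
)
from .references import ReferenceTable, ToxicologyTable, default_toxicology_table
from .samples import (
    METALS,
    SampleTable,
    correlation_matrix,
    read_sample_table,
    summarize_samples,
    write_sample_table,
)
from .synthetic import StudyProfile, default_liuye_profile, generate_samples

__all__ = ["PipelineConfig", "PipelineError", "run_full_analysis"]

logger = logging.getLogger(__name__)

#: candidate set for family selection (continuous moment-fittable families)
DEFAULT_CANDIDATES = tuple(CONTINUOUS_FAMILIES)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    input: str = "synthetic"  # "synthetic" or a sample CSV path
    profile: Optional[StudyProfile] = None
    reference: Optional[ReferenceTable] = None
    toxicology: Optional[ToxicologyTable] = None
    er_mode: str = "paper_division"
    seed: int = 0
    n_iterations: int = 10_000
    ci_level: float = 0.95
    outdir: str = "sedrisk_report"

    def resolve(self) -> "PipelineConfig":
        if self.profile is None:
            self.profile = default_liuye_profile()
        if self.reference is None:
            self.reference = self.profile.reference_table()
        if self.toxicology is None:
            self.toxicology = default_toxicology_table()
        if self.er_mode not in ("paper_division", "hakanson_product"):
            raise ValueError(f"unknown er_mode {self.er_mode!r}")
        return self


def _concentration_draws(
    specs: dict[str, DistributionSpec], n: int, seed: int
) -> dict[str, np.ndarray]:
    return {m: specs[m].rvs(n, substream(seed, f"conc:{m}")) for m in METALS}


def run_full_analysis(config: PipelineConfig) -> dict[str, Path]:
    """Run the whole pipeline; returns a name -> path map of the bundle."""
    config.resolve()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    bundle: dict[str, Path] = {}

    def emit(name: str, filename: str, writer) -> None:
        path = outdir / filename
        writer(path)
        written.append(path)
        bundle[name] = path

    stage = "setup"
    try:
        # ---- samples -----------------------------------------------------
        stage = "samples"
        if config.input == "synthetic":
            table = generate_samples(config.profile, seed=config.seed)
        else:
            table = read_sample_table(config.input)
        emit("samples", "samples.csv", lambda p: write_sample_table(table, p))

        # ---- summary statistics -----------------------------------------
        stage = "summary"
        stats = summarize_samples(table)
        emit("summary_stats", "summary_stats.csv", lambda p: stats.to_csv(p))
        corr = correlation_matrix(table)
        emit("correlation", "correlation.csv", lambda p: corr.to_csv(p))

        # ---- distribution fitting ---------------------------------------
        stage = "fit"
        fit_rows = []
        fitted_specs: dict[str, dict] = {}
        for metal in METALS:
            ranked = select_family(table.concentrations()[metal], DEFAULT_CANDIDATES)
            for rank, (fam, spec, a2) in enumerate(ranked):
                fit_rows.append(
                    {"metal": metal, "rank": rank, "family": fam, "a2": a2}
                )
            fitted_specs[metal] = ranked[0][1].to_dict()
        emit(
            "fitted_families",
            "fitted_families.csv",
            lambda p: pd.DataFrame(fit_rows).to_csv(p, index=False),
        )
        emit(
            "fitted_specs",
            "fitted_specs.json",
            lambda p: p.write_text(json.dumps(fitted_specs, indent=2)),
        )

        # ---- deterministic indices --------------------------------------
        stage = "indices"
        index_table = compute_index_table(table, config.reference, er_mode=config.er_mode)
        emit(
            "indices_per_site",
            "indices_per_site.csv",
            lambda p: index_table.to_csv(p, index=False),
        )

        # ---- Monte Carlo index summaries --------------------------------
        stage = "mc_indices"
        specs = {m: config.profile.concentration_spec(m) for m in METALS}
        mc = MonteCarloConfig(
            n_iterations=config.n_iterations, seed=config.seed, ci_level=config.ci_level
        )
        conc_draws = _concentration_draws(specs, mc.n_iterations, mc.seed)
        al_ratio = config.profile.al_ratio_model.rvs(
            mc.n_iterations, substream(mc.seed, "al_ratio")
        )
        al_ratio = np.clip(al_ratio, 1e-12, None)
        mc_rows, prob_rows = [], []
        er_draws: dict[str, np.ndarray] = {}
        for metal in METALS:
            bg = config.reference.background[metal]
            tr = config.reference.toxic_response[metal]
            draws = conc_draws[metal]
            results = {
                "igeo": (igeo(draws, bg), IGEO_SCHEME),
                "ef": (contamination_factor(draws, bg) / al_ratio, EF_SCHEME),
                "cf": (contamination_factor(draws, bg), None),
                "er": (
                    single_metal_risk(
                        contamination_factor(draws, bg), tr, mode=config.er_mode
                    ),
                    None,
                ),
            }
            er_draws[metal] = results["er"][0]
            for name, (vals, scheme) in results.items():
                res = MCResult.from_draws(vals, ci_level=mc.ci_level)
                mc_rows.append({"index": name, "metal": metal, **res.to_dict()})
                if scheme is not None:
                    for label, p_ in class_probabilities(res, scheme).items():
                        prob_rows.append(
                            {"index": name, "metal": metal, "label": label, "probability": p_}
                        )
        ri_res = MCResult.from_draws(
            np.sum([er_draws[m] for m in METALS], axis=0), ci_level=mc.ci_level
        )
        mc_rows.append({"index": "ri", "metal": "all", **ri_res.to_dict()})
        for label, p_ in class_probabilities(ri_res, RI_SCHEME).items():
            prob_rows.append(
                {"index": "ri", "metal": "all", "label": label, "probability": p_}
            )
        emit(
            "mc_indices",
            "mc_indices.csv",
            lambda p: pd.DataFrame(mc_rows).to_csv(p, index=False),
        )
        emit(
            "mc_class_probabilities",
            "mc_class_probabilities.csv",
            lambda p: pd.DataFrame(prob_rows).to_csv(p, index=False),
        )

        # ---- health risk -------------------------------------------------
        stage = "health_risk"
        mean_conc = {m: float(stats.loc[m, "mean"]) for m in METALS}
        profiles = default_profiles()
        health_rows, sens_rows = [], []
        for group in GROUPS:
            for route in ROUTES:
                hi_res = hazard_index_mc(
                    mean_conc, profiles[group], route, mc, config.toxicology
                )
                row = {
                    "group": group,
                    "route": route,
                    "quantity": "HI",
                    **hi_res.to_dict(),
                    "p_exceed": exceedance_probability(hi_res, 1.0),
                    "class": "potential" if hi_res.mean > 1 else "negligible",
                }
                health_rows.append(row)
                for name, contrib in sensitivity_contribution(
                    hi_res.input_draws, hi_res.draws
                ).items():
                    sens_rows.append(
                        {
                            "group": group,
                            "route": route,
                            "quantity": "HI",
                            "variable": name,
                            "contribution_pct": contrib,
                        }
                    )
                tcr_res = total_carcinogenic_risk_mc(
                    mean_conc, profiles[group], route, mc, config.toxicology
                )
                if tcr_res is not None:
                    health_rows.append(
                        {
                            "group": group,
                            "route": route,
                            "quantity": "TCR",
                            **tcr_res.to_dict(),
                            "p_exceed": exceedance_probability(tcr_res, 1e-4),
                            "class": classify_tcr(tcr_res.mean),
                        }
                    )
        emit(
            "health_mc",
            "health_mc.csv",
            lambda p: pd.DataFrame(health_rows).to_csv(p, index=False),
        )
        emit(
            "sensitivity",
            "sensitivity.csv",
            lambda p: pd.DataFrame(sens_rows).to_csv(p, index=False),
        )

        # ---- run log -----------------------------------------------------
        stage = "log"
        emit(
            "run_log",
            "run.log",
            lambda p: p.write_text(
                "\n".join(
                    [
                        f"sedrisk version: {__version__}",
                        f"input: {config.input}",
                        f"seed: {config.seed}",
                        f"n_iterations: {config.n_iterations}",
                        f"ci_level: {config.ci_level}",
                        f"er_mode: {config.er_mode}",
                        f"n_sites: {table.n_sites}",
                    ]
                )
                + "\n"
            ),
        )
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:  # pragma: no cover
                pass
        raise PipelineError(stage, exc) from exc
    return bundle
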