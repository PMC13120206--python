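"""Deterministic pollution and ecological-risk indices with grading schemes.

Implements the geo-accumulation index (Igeo, Müller), the enrichment factor
(EF, aluminium-normalized double ratio), the contamination factor (Cf), the
single-metal potential ecological risk (Er) and the comprehensive risk index
(RI = sum of Er), together with their step-function classification schemes.

Note on Er: the study this package reproduces computes Er = Tr / Cf (its
printed results are numerically consistent only with that division form),
whereas Hakanson's canonical definition is Er = Tr * Cf.  Both are provided;
``mode="paper_division"`` is the default, ``mode="hakanson_product"`` selects
the literature-standard product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .references import ReferenceTable
from .samples import METALS, SampleTable

__all__ = [
    "ClassificationScheme",
    "EF_SCHEME",
    "IGEO_SCHEME",
    "RI_SCHEME",
    "classify_ef",
    "classify_igeo",
    "compute_index_table",
    "contamination_factor",
    "enrichment_factor",
    "igeo",
    "risk_index",
    "single_metal_risk",
]

logger = logging.getLogger(__name__)

ER_MODES = ("paper_division", "hakanson_product")


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered breakpoints with upper-closed intervals.

    ``classify(x)`` maps x to grade g where grade 0 is (-inf, b1], grade 1 is
    (b1, b2], ..., and the last grade is (b_last, inf).  Every breakpoint
    itself maps to the *lower* grade (the "<=" convention).
    """

    breakpoints: tuple
    labels: tuple

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.labels) != len(bp) + 1:
            raise ValueError("need exactly one more label than breakpoints")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "labels", tuple(self.labels))

    def classify(self, x: float) -> tuple[int, str]:
        if not np.isfinite(x):
            raise ValueError(f"cannot classify non-finite value {x!r}")
        grade = int(np.searchsorted(self.breakpoints, x, side="left"))
        return grade, self.labels[grade]

    def classify_many(self, x) -> np.ndarray:
        """Vectorized grades for an array of values."""
        arr = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("cannot classify non-finite values")
        return np.searchsorted(self.breakpoints, arr, side="left")


#: Müller geo-accumulation grades
IGEO_SCHEME = ClassificationScheme(
    breakpoints=(0.0, 1.0, 2.0, 3.0, 4.0),
    labels=(
        "Uncontaminated",
        "Slightly contaminated",
        "Moderately contaminated",
        "Moderately to heavily contaminated",
        "Heavily contaminated",
        "Extremely contaminated",
    ),
)

#: enrichment-factor grades
EF_SCHEME = ClassificationScheme(
    breakpoints=(1.0, 2.0, 5.0, 20.0, 40.0),
    labels=(
        "Uncontaminated",
        "Slightly contaminated",
        "Moderately contaminated",
        "Moderately/Heavily contaminated",
        "Heavily contaminated",
        "Extremely contaminated",
    ),
)

#: comprehensive potential-ecological-risk grades
RI_SCHEME = ClassificationScheme(
    breakpoints=(150.0, 300.0, 600.0, 1200.0),
    labels=(
        "Slight risk",
        "Moderate risk",
        "Higher risk",
        "High risk",
        "Extremely high risk",
    ),
)


def _require_positive(**values) -> None:
    for name, v in values.items():
        arr = np.asarray(v, dtype=float)
        if np.any(~(arr > 0)):
            raise ValueError(f"{name} must be strictly positive")


def igeo(c, c0):
    """Geo-accumulation index: log2 of c over 1.5x the background c0."""
    _require_positive(c=c, c0=c0)
    return np.log2(np.asarray(c, dtype=float) / (1.5 * np.asarray(c0, dtype=float)))


def classify_igeo(x: float) -> tuple[int, str]:
    return IGEO_SCHEME.classify(x)


def enrichment_factor(ci, c_ref_sample, bg_i, bg_ref):
    """EF = (ci / c_ref_sample) / (bg_i / bg_ref), reference element Al."""
    _require_positive(ci=ci, c_ref_sample=c_ref_sample, bg_i=bg_i, bg_ref=bg_ref)
    ci = np.asarray(ci, dtype=float)
    return (ci / np.asarray(c_ref_sample, dtype=float)) / (
        np.asarray(bg_i, dtype=float) / np.asarray(bg_ref, dtype=float)
    )


def classify_ef(x: float) -> tuple[int, str]:
    return EF_SCHEME.classify(x)


def contamination_factor(ci, cn_i):
    """Cf = measured concentration over background."""
    _require_positive(ci=ci, cn_i=cn_i)
    return np.asarray(ci, dtype=float) / np.asarray(cn_i, dtype=float)


def single_metal_risk(cf, tr, mode: str = "paper_division"):
    """Single-metal potential ecological risk Er.

    ``paper_division`` (default): Er = tr / cf, the form this package's
    source study prints and its results follow.  ``hakanson_product``:
    Er = tr * cf, Hakanson's canonical definition.
    """
    _require_positive(cf=cf, tr=tr)
    if mode not in ER_MODES:
        raise ValueError(f"unknown Er mode {mode!r}; expected one of {ER_MODES}")
    cf = np.asarray(cf, dtype=float)
    tr = np.asarray(tr, dtype=float)
    return tr / cf if mode == "paper_division" else tr * cf


def risk_index(er_values: Mapping[str, float]) -> tuple[float, str]:
    """RI = sum of Er over the nine metals, graded on the RI scheme."""
    missing = [m for m in METALS if m not in er_values]
    if missing:
        raise ValueError(f"missing Er value(s) for: {', '.join(missing)}")
    ri = float(sum(float(er_values[m]) for m in METALS))
    _, label = RI_SCHEME.classify(ri)
    return ri, label


def compute_index_table(
    table: SampleTable,
    reference: Optional[ReferenceTable] = None,
    er_mode: str = "paper_division",
) -> pd.DataFrame:
    """All per-site, per-metal indices as one tidy frame.

    Columns: site_id, metal, igeo, igeo_grade, ef (NaN without Al), ef_grade,
    cf, er, ri, ri_label.  ``ri`` repeats the site total on each of the
    site's rows so the frame stays tidy.
    """
    from .references import default_reference_table

    ref = reference if reference is not None else default_reference_table()
    conc = table.concentrations()
    al = table.al() if table.has_al else None
    if al is None:
        logger.warning("no Al column: enrichment factors omitted")

    rows = []
    for site, row in conc.iterrows():
        ers = {}
        site_rows = []
        for metal in METALS:
            c = float(row[metal])
            bg = ref.background[metal]
            ig = float(igeo(c, bg))
            cf = float(contamination_factor(c, bg))
            er = float(single_metal_risk(cf, ref.toxic_response[metal], mode=er_mode))
            ers[metal] = er
            if al is not None and ref.al_background is not None:
                ef = float(enrichment_factor(c, float(al.loc[site]), bg, ref.al_background))
                ef_grade = EF_SCHEME.classify(ef)[0]
            else:
                ef, ef_grade = np.nan, pd.NA
            site_rows.append(
                {
                    "site_id": site,
                    "metal": metal,
                    "igeo": ig,
                    "igeo_grade": IGEO_SCHEME.classify(ig)[0],
                    "ef": ef,
                    "ef_grade": ef_grade,
                    "cf": cf,
                    "er": er,
                }
            )
        ri, ri_label = risk_index(ers)
        for r in site_rows:
            r["ri"] = ri
            r["ri_label"] = ri_label
        rows.extend(site_rows)
    return pd.DataFrame(rows)
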