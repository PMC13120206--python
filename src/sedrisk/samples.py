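"""Sample-table data model, CSV I/O, summary statistics and correlation.

The raw input of the pipeline is a per-site table of sediment heavy-metal
concentrations (mg/kg dry weight) for the nine metals As, Cd, Cr, Cu, Hg,
Mn, Ni, Pb, Zn, with an optional aluminium column (the conservative
reference element used by the enrichment factor) and optional decorative
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "METALS",
    "SampleTable",
    "SchemaError",
    "ValidationError",
    "correlation_matrix",
    "read_sample_table",
    "summarize_samples",
    "write_sample_table",
]

#: canonical metal order used throughout the package
METALS = ("As", "Cd", "Cr", "Cu", "Hg", "Mn", "Ni", "Pb", "Zn")

_SITE_COL = "site_id"
_AL_COL = "Al"
_COORD_COLS = ("x", "y")


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """A value violates the data model (e.g. non-positive concentration)."""


@dataclass(frozen=True)
class SampleTable:
    """Validated per-site concentration table.

    ``data`` holds one row per site with a ``site_id`` column, the nine metal
    columns (mg/kg, strictly positive), and optionally ``Al`` and ``x``/``y``
    coordinates.  Row order is preserved from the source.
    """

    data: pd.DataFrame

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, require_al: bool = False) -> "SampleTable":
        if _SITE_COL not in df.columns:
            raise SchemaError(f"missing required column {_SITE_COL!r}")
        missing = [m for m in METALS if m not in df.columns]
        if missing:
            raise SchemaError(f"missing metal column(s): {', '.join(missing)}")
        if require_al and _AL_COL not in df.columns:
            raise SchemaError(f"missing required column {_AL_COL!r}")
        if df[_SITE_COL].duplicated().any():
            dupes = df.loc[df[_SITE_COL].duplicated(), _SITE_COL].tolist()
            raise ValidationError(f"duplicate site id(s): {dupes}")
        value_cols = list(METALS) + ([_AL_COL] if _AL_COL in df.columns else [])
        out = df.copy()
        for col in value_cols:
            numeric = pd.to_numeric(out[col], errors="coerce")
            bad = numeric.isna() | (numeric <= 0)
            if bad.any():
                site = out.loc[bad, _SITE_COL].iloc[0]
                raise ValidationError(
                    f"non-positive or non-numeric concentration for metal "
                    f"{col!r} at site {site!r}"
                )
            out[col] = numeric.astype(float)
        keep = [_SITE_COL] + value_cols + [c for c in _COORD_COLS if c in out.columns]
        return cls(out[keep].reset_index(drop=True))

    @property
    def site_ids(self) -> list[str]:
        return self.data[_SITE_COL].astype(str).tolist()

    @property
    def has_al(self) -> bool:
        return _AL_COL in self.data.columns

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def concentrations(self) -> pd.DataFrame:
        """Metal columns only, indexed by site id (canonical metal order)."""
        return self.data.set_index(_SITE_COL)[list(METALS)]

    def al(self) -> pd.Series:
        if not self.has_al:
            raise SchemaError("table has no Al reference-element column")
        return self.data.set_index(_SITE_COL)[_AL_COL]


def read_sample_table(path, require_al: bool = False) -> SampleTable:
    """Read and validate a sample CSV (comma, dot decimal, header required)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return SampleTable.from_dataframe(pd.read_csv(path), require_al=require_al)


def write_sample_table(table: SampleTable, path) -> None:
    """Write a sample table as CSV at full stored precision (round-trips)."""
    table.data.to_csv(path, index=False)


def summarize_samples(table: SampleTable) -> pd.DataFrame:
    """Per-metal min/max/median/mean/sd/cv (sd uses the n-1 denominator).

    Returns a DataFrame indexed by metal with columns
    ``min, max, median, mean, sd, cv``; ``cv`` is in percent of the mean.
    """
    if table.n_sites < 2:
        raise ValidationError("summary statistics require at least 2 sites (sd undefined)")
    conc = table.concentrations()
    out = pd.DataFrame(
        {
            "min": conc.min(),
            "max": conc.max(),
            "median": conc.median(),
            "mean": conc.mean(),
            "sd": conc.std(ddof=1),
        }
    )
    out["cv"] = np.where(out["mean"] > 0, 100.0 * out["sd"] / out["mean"], 0.0)
    out.index.name = "metal"
    return out


def correlation_matrix(table: SampleTable, method: str = "pearson") -> pd.DataFrame:
    """Pearson correlation among the nine metal columns (unit diagonal)."""
    if method != "pearson":
        raise ValueError(f"unsupported correlation method {method!r}")
    if table.n_sites < 3:
        raise ValidationError("correlation requires at least 3 sites")
    conc = table.concentrations()
    constant = conc.columns[conc.std(ddof=0) == 0].tolist()
    if constant:
        raise ValidationError(f"constant column(s): {', '.join(constant)}")
    corr = conc.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
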