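"""Reference constants: geochemical backgrounds, toxic-response factors,
and USEPA toxicology values (reference doses, slope factors, dermal
absorption fractions).

Defaults encode the Dongting Lake water-system background values and the
standard Hakanson toxic-response weights for the nine metals, plus the
route-specific RfD/SF table used by the health-risk model.  Everything is
overridable from CSV or YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .samples import METALS

__all__ = [
    "DEFAULT_AL_BACKGROUND",
    "ReferenceTable",
    "ToxicologyTable",
    "default_reference_table",
    "default_toxicology_table",
]

# Dongting Lake water-system geochemical background, mg/kg dry weight
_BACKGROUND = {
    "As": 12.90,
    "Cd": 0.33,
    "Cr": 44.00,
    "Cu": 20.20,
    "Hg": 0.047,
    "Mn": 450.00,
    "Ni": 21.20,
    "Pb": 23.30,
    "Zn": 83.30,
}

# Hakanson toxic-response factors (dimensionless)
_TOXIC_RESPONSE = {
    "As": 10.0,
    "Cd": 30.0,
    "Cr": 2.0,
    "Cu": 5.0,
    "Hg": 40.0,
    "Mn": 1.0,
    "Ni": 5.0,
    "Pb": 5.0,
    "Zn": 1.0,
}

#: nominal aluminium background, mg/kg (typical upper-crust abundance).
#: Only the sample/background Al *ratio* enters the enrichment factor, so
#: this scale constant cancels out of every EF value.
DEFAULT_AL_BACKGROUND = 66_000.0

# Ingestion / dermal reference doses, mg/(kg*d)
_RFD_ING = {
    "As": 3.00e-4,
    "Cd": 1.00e-3,
    "Cr": 3.00e-3,
    "Cu": 4.00e-2,
    "Hg": 3.00e-4,
    "Mn": 4.60e-2,
    "Ni": 2.00e-2,
    "Pb": 3.50e-3,
    "Zn": 3.50e-1,
}
_RFD_DERM = {
    "As": 1.23e-4,
    "Cd": 1.00e-5,
    "Cr": 6.00e-5,
    "Cu": 1.20e-2,
    "Hg": 2.10e-5,
    "Mn": 1.84e-3,
    "Ni": 5.40e-3,
    "Pb": 5.25e-3,
    "Zn": 6.00e-2,
}

# Cancer slope factors, (mg/(kg*d))^-1; present only where published
_SF_ING = {"As": 1.50, "Cd": 1.80, "Cr": 5.00e-1, "Pb": 8.50e-3}
_SF_DERM = {"As": 1.50, "Cd": 3.80e-1}

# Dermal absorption fractions (dimensionless)
_ABS = {
    "As": 0.03,
    "Cd": 0.14,
    "Cr": 0.001,
    "Cu": 0.1,
    "Hg": 0.50,
    "Mn": 0.01,
    "Ni": 0.35,
    "Pb": 0.006,
    "Zn": 0.02,
}


def _check_complete(name: str, mapping: Mapping[str, float]) -> dict[str, float]:
    missing = [m for m in METALS if m not in mapping]
    if missing:
        raise ValueError(f"{name}: missing entries for {', '.join(missing)}")
    bad = [m for m in METALS if not mapping[m] > 0]
    if bad:
        raise ValueError(f"{name}: non-positive values for {', '.join(bad)}")
    return {m: float(mapping[m]) for m in METALS}


@dataclass(frozen=True)
class ReferenceTable:
    """Geochemical background values and toxic-response factors."""

    background: dict[str, float]
    toxic_response: dict[str, float]
    al_background: Optional[float] = DEFAULT_AL_BACKGROUND

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "background", _check_complete("background", self.background)
        )
        object.__setattr__(
            self, "toxic_response", _check_complete("toxic_response", self.toxic_response)
        )
        if self.al_background is not None and not self.al_background > 0:
            raise ValueError("al_background must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "ReferenceTable":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            background=raw["background"],
            toxic_response=raw["toxic_response"],
            al_background=raw.get("al_background", DEFAULT_AL_BACKGROUND),
        )


@dataclass(frozen=True)
class ToxicologyTable:
    """Route-specific RfD/SF/ABS constants for the health-risk model.

    Slope factors exist only for the published metal/route pairs (ingestion:
    As, Cd, Cr, Pb; dermal: As, Cd); elsewhere carcinogenic risk is simply
    not computed.
    """

    rfd_ing: dict[str, float] = field(default_factory=lambda: dict(_RFD_ING))
    rfd_derm: dict[str, float] = field(default_factory=lambda: dict(_RFD_DERM))
    sf_ing: dict[str, float] = field(default_factory=lambda: dict(_SF_ING))
    sf_derm: dict[str, float] = field(default_factory=lambda: dict(_SF_DERM))
    abs_dermal: dict[str, float] = field(default_factory=lambda: dict(_ABS))

    def __post_init__(self) -> None:
        _check_complete("rfd_ing", self.rfd_ing)
        _check_complete("rfd_derm", self.rfd_derm)
        _check_complete("abs_dermal", self.abs_dermal)
        if not all(0 < v <= 1 for v in self.abs_dermal.values()):
            raise ValueError("abs_dermal fractions must lie in (0, 1]")

    def rfd(self, metal: str, route: str) -> float:
        table = self.rfd_ing if route == "ingestion" else self.rfd_derm
        if metal not in table:
            raise KeyError(f"no {route} RfD for {metal}")
        return table[metal]

    def sf(self, metal: str, route: str) -> Optional[float]:
        """Slope factor, or None where no published value exists."""
        table = self.sf_ing if route == "ingestion" else self.sf_derm
        return table.get(metal)


def default_reference_table() -> ReferenceTable:
    return ReferenceTable(background=dict(_BACKGROUND), toxic_response=dict(_TOXIC_RESPONSE))


def default_toxicology_table() -> ToxicologyTable:
    return ToxicologyTable()
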