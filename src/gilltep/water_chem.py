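"""Water-composition data model, amendment arithmetic and plausibility checks.

Concentrations are stored in umol/L throughout (the convention of dilute
tropical freshwaters); equivalents use the unsigned valence.  Two
diagnostics support quality control of a measured water table:

* a charge balance (cation minus anion equivalents) — dilute natural
  waters typically show a positive gap because HCO3- and organic anions
  are not in the measured ion set;
* a Kohlrausch infinite-dilution conductivity predictor, sum of limiting
  equivalent conductances times equivalent concentrations, used as a
  sanity check against the measured conductivity (no temperature or
  ionic-strength correction is attempted, so agreement within ~20% is the
  expectation, not a fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .constants import valence
from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "WaterComposition",
    "LIMITING_EQUIV_CONDUCTANCE",
    "SALTS",
    "charge_balance",
    "amend",
    "required_addition",
    "predict_conductivity",
]

#: Limiting (infinite-dilution) equivalent conductances at 25 degC,
#: S cm^2 eq^-1, standard tabulated values.
LIMITING_EQUIV_CONDUCTANCE: dict[str, float] = {
    "Na": 50.1,
    "K": 73.5,
    "NH4": 73.5,
    "H": 349.8,
    "Ca": 59.5,
    "Mg": 53.1,
    "Cl": 76.3,
    "OH": 198.0,
}

#: Salts available for amendment: name -> (cation, anion).
SALTS: dict[str, tuple[str, str]] = {
    "NaCl": ("Na", "Cl"),
    "NH4Cl": ("NH4", "Cl"),
}


@dataclass(frozen=True)
class WaterComposition:
    """One water's measured makeup: pH, organic/inorganic carbon, ions (umol/L)."""

    name: str
    ph: float
    doc_mg_l: float = 0.0
    dic_mg_l: float = 0.0
    ions: Mapping[str, float] = field(default_factory=dict)
    conductivity_us_cm: float | None = None
    temperature: float = 27.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ph < 14.0):
            raise InvalidInputError(f"pH must be in (0, 14), got {self.ph}")
        for ion, c in self.ions.items():
            valence(ion)
            if not (c >= 0.0 and math.isfinite(c)):
                raise InvalidInputError(f"[{ion}] must be >= 0 and finite, got {c}")
        object.__setattr__(self, "ions", dict(self.ions))

    @property
    def ions_mmol(self) -> dict[str, float]:
        """Ion map converted to mmol/L (for the electrochemical engine)."""
        return {ion: c / 1000.0 for ion, c in self.ions.items()}


def charge_balance(water: WaterComposition) -> float:
    """Charge balance in ueq/L: cation equivalents minus anion equivalents.

    A positive gap indicates anions (typically HCO3- and organic anions)
    missing from the measured set; the gap is reported, not imputed.
    """
    cations = sum(valence(i) * c for i, c in water.ions.items() if valence(i) > 0)
    anions = sum(abs(valence(i)) * c for i, c in water.ions.items() if valence(i) < 0)
    return cations - anions


def amend(water: WaterComposition, salt: str, addition: float) -> WaterComposition:
    """Add *addition* umol/L of a 1:1 salt, incrementing both constituent ions."""
    if salt not in SALTS:
        raise InvalidInputError(f"unknown salt {salt!r}; supported: {sorted(SALTS)}")
    if not (addition >= 0.0 and math.isfinite(addition)):
        raise InvalidInputError(f"addition must be >= 0, got {addition}")
    if addition == 0.0:
        return water
    cation, anion = SALTS[salt]
    ions = dict(water.ions)
    ions[cation] = ions.get(cation, 0.0) + addition
    ions[anion] = ions.get(anion, 0.0) + addition
    return replace(
        water,
        name=f"{water.name} + {addition:g} umol/L {salt}",
        ions=ions,
        conductivity_us_cm=None,  # measured value no longer applies
    )


def required_addition(water: WaterComposition, target_na: float) -> float:
    """Salt addition (umol/L) needed to raise the water's Na+ to *target_na*."""
    current = water.ions.get("Na", 0.0)
    if target_na < current:
        raise InvalidInputError(
            f"target Na {target_na} umol/L is below the background {current} umol/L"
        )
    return target_na - current


def predict_conductivity(
    water: WaterComposition,
    table: Mapping[str, float] | None = None,
    background: float = 0.0,
) -> float:
    """Kohlrausch infinite-dilution conductivity estimate, uS/cm.

    sum_i lambda0_i |z_i| c_i (c in umol/L) plus an optional measured
    *background* for constituents not in the ion map.  An order-of-magnitude
    plausibility check, not a calibrated model: limiting 25 degC
    conductances, no ionic-strength correction.
    """
    if table is None:
        table = LIMITING_EQUIV_CONDUCTANCE
    total = background
    for ion, c in water.ions.items():
        if ion not in table:
            raise ConfigurationError(f"no limiting conductance tabulated for ion {ion!r}")
        # umol/L * |z| = ueq/L; * lambda0 [S cm^2/eq] / 1000 -> uS/cm
        total += table[ion] * abs(valence(ion)) * c / 1000.0
    return total
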