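"""Nernst/GHK engine for trans-gill electrochemical gradients.

In dilute fresh water the potential across the fish gill (TEP, blood side
relative to external water defined as 0 mV) behaves as a simple diffusion
potential: it arises from the differential passive permeability of the
epithelium to plasma cations (mainly Na+) versus anions (mainly Cl-), with
no electrogenic pump term.  This module provides the quantitative machinery
for that picture:

* temperature-dependent Nernst slopes and single-ion equilibrium potentials,
* partitioning of an ion's electrochemical gradient into its chemical
  (Nernst) and electrical (TEP) components, including the "equivalent
  internal concentration" transform,
* the Goldman-Hodgkin-Katz (GHK) voltage equation for monovalent ions, both
  forward (permeabilities -> potential) and inverted in closed form
  (potential -> P_Na/P_Cl ratio).

Conventions
-----------
* All potentials are in mV, inside (blood/peritoneal fluid) relative to the
  external water taken as 0 mV.
* Activities are taken equal to concentrations: the waters of interest are
  at most a few mmol/L ionic strength, so the ideal-dilute approximation is
  adequate and no Debye-Hueckel correction is applied.
* Temperature enters every expression through T_K = T_C + 273.15 only;
  there is no baked-in "room temperature" constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

from .constants import CONSTANTS, PhysicalConstants, is_monovalent, valence
from .exceptions import (
    DegenerateSolutionError,
    InfeasiblePotentialError,
    InvalidInputError,
    UnsupportedModelError,
)

__all__ = [
    "PlasmaComposition",
    "GHKPermeabilitySet",
    "GradientPartition",
    "DrivingForceShift",
    "DEFAULT_PLASMA",
    "nernst_slope",
    "nernst_potential",
    "partition_gradient",
    "driving_force_shift",
    "ghk_voltage",
    "ghk_fit_permeability_ratio",
]

#: Numerical tolerance (mV-scale) below which the GHK inverse problem is
#: treated as degenerate rather than solvable.
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class PlasmaComposition:
    """Internal (blood plasma) ion concentrations in mmol/L.

    The plasma Na+ concentration of 158 mmol/L is the literature value for
    the study species; Cl- 130 mmol/L and K+ 3 mmol/L are generic teleost
    plasma values supplied as overridable defaults, not measurements.
    """

    concentrations: Mapping[str, float]
    temperature: float = 27.0

    def __post_init__(self) -> None:
        if "Na" not in self.concentrations:
            raise InvalidInputError("plasma composition must include Na")
        for ion, c in self.concentrations.items():
            valence(ion)
            if not (c > 0.0 and math.isfinite(c)):
                raise InvalidInputError(f"plasma [{ion}] must be positive and finite, got {c}")
        object.__setattr__(self, "concentrations", dict(self.concentrations))


#: Default plasma assumed throughout: Na measured-for-species, Cl and K generic.
DEFAULT_PLASMA = PlasmaComposition({"Na": 158.0, "Cl": 130.0, "K": 3.0})


@dataclass(frozen=True)
class GHKPermeabilitySet:
    """Relative permeabilities of monovalent ions, with P_Cl == 1 as reference."""

    relative_permeability: Mapping[str, float]
    reference_ion: str = "Cl"

    def __post_init__(self) -> None:
        perms = dict(self.relative_permeability)
        if self.reference_ion not in perms:
            raise InvalidInputError(f"reference ion {self.reference_ion!r} missing from permeability set")
        if perms[self.reference_ion] != 1.0:
            raise InvalidInputError(f"reference ion {self.reference_ion!r} must have permeability 1")
        for ion, p in perms.items():
            if not is_monovalent(ion):
                raise UnsupportedModelError(
                    f"GHK permeability set is restricted to monovalent ions; got {ion!r}"
                )
            if not (p >= 0.0 and math.isfinite(p)):
                raise InvalidInputError(f"permeability of {ion!r} must be >= 0, got {p}")
        object.__setattr__(self, "relative_permeability", perms)


@dataclass(frozen=True)
class GradientPartition:
    """Decomposition of one ion's electrochemical gradient at a given TEP.

    Attributes
    ----------
    tep : float
        Transepithelial potential, mV (inside vs. water = 0).
    nernst_potential : float
        Equilibrium potential of the ion, mV.
    driving_force : float
        ``tep - nernst_potential``; for a cation a positive value favours
        net efflux.
    electrical_fraction : float
        ``|tep| / |nernst_potential|`` — the share of the (chemical)
        gradient contributed by the TEP when both have the same sign.  NaN
        when the Nernst potential is zero but the TEP is not.
    equivalent_internal_concentration : float
        The internal concentration that, at TEP = 0, would produce the same
        driving force (same unit as the concentrations supplied).
    """

    tep: float
    nernst_potential: float
    driving_force: float
    electrical_fraction: float
    equivalent_internal_concentration: float

    @property
    def electrical_fraction_percent(self) -> float:
        """Electrical fraction expressed in percent, full precision."""
        return self.electrical_fraction * 100.0

    @property
    def electrical_fraction_percent_rounded(self) -> int:
        """Electrical fraction in percent, rounded to the nearest integer."""
        return int(round(self.electrical_fraction_percent))


@dataclass(frozen=True)
class DrivingForceShift:
    """Result of shifting a positive driving force by a TEP change."""

    new_driving: float
    percent_reduction: float
    sign_reversal: bool = False

    @property
    def percent_reduction_rounded(self) -> int:
        return int(round(self.percent_reduction))


def nernst_slope(
    temperature: float,
    base: Literal["natural", "decadic"] = "natural",
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Nernst slope RT/F at *temperature* (degC), in mV.

    ``base="natural"`` gives mV per e-fold concentration ratio,
    ``base="decadic"`` gives mV per decade (the familiar ~59 mV near room
    temperature for a monovalent ion).
    """
    t_k = constants.kelvin(temperature)
    slope = 1000.0 * constants.R * t_k / constants.F
    if base == "natural":
        return slope
    if base == "decadic":
        return math.log(10.0) * slope
    raise InvalidInputError(f"base must be 'natural' or 'decadic', got {base!r}")


def nernst_potential(
    c_out: float,
    c_in: float,
    z: int,
    temperature: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Single-ion equilibrium potential, mV (inside vs. outside = 0).

    E = (RT/zF) ln(c_out/c_in).  Both concentrations must be positive and in
    the same unit; the unit cancels.  Antisymmetric under swapping sides.
    """
    if z == 0:
        raise InvalidInputError("valence must be nonzero")
    for label, c in (("c_out", c_out), ("c_in", c_in)):
        if not (c > 0.0 and math.isfinite(c)):
            raise InvalidInputError(f"{label} must be positive and finite, got {c}")
    slope = nernst_slope(temperature, "natural", constants)
    return slope / z * math.log(c_out / c_in)


def partition_gradient(
    tep: float,
    c_out: float,
    c_in: float,
    z: int,
    temperature: float,
    constants: PhysicalConstants = CONSTANTS,
) -> GradientPartition:
    """Partition the electrochemical gradient for one ion at a measured TEP.

    The total outward driving force on the ion (mV) is ``tep - E_ion``; the
    electrical fraction quantifies how much of the chemical gradient the TEP
    offsets.  The equivalent internal concentration re-expresses the
    *reduced* gradient as a fictitious plasma concentration at TEP = 0 —
    a TEP of -22.3 mV against a 158 mmol/L plasma Na gradient "looks like"
    only ~67 mmol/L of plasma Na, because of the logarithmic form of the
    Nernst relation.

    Concentrations may be in any single common unit; ``c_out`` and ``c_in``
    and the equivalent concentration all share it.
    """
    if not math.isfinite(tep):
        raise InvalidInputError(f"tep must be finite, got {tep}")
    e_ion = nernst_potential(c_out, c_in, z, temperature, constants)
    driving = tep - e_ion
    if e_ion == 0.0:
        fraction = 0.0 if tep == 0.0 else math.nan
    else:
        fraction = abs(tep) / abs(e_ion)
    slope = nernst_slope(temperature, "natural", constants)
    equivalent = c_out * math.exp(driving * z / slope)
    return GradientPartition(
        tep=tep,
        nernst_potential=e_ion,
        driving_force=driving,
        electrical_fraction=fraction,
        equivalent_internal_concentration=equivalent,
    )


def driving_force_shift(initial_driving: float, delta_tep: float) -> DrivingForceShift:
    """Shift a positive outward driving force by a TEP change.

    A hyperpolarising TEP change (``delta_tep < 0`` for a cation-loss
    gradient) reduces the driving force linearly; the percent reduction is
    reported relative to the initial gradient.  If the shift overshoots and
    reverses the sign of the driving force, the result carries a
    ``sign_reversal`` flag instead of raising.
    """
    if not (initial_driving > 0.0 and math.isfinite(initial_driving)):
        raise InvalidInputError(f"initial driving force must be positive, got {initial_driving}")
    if not math.isfinite(delta_tep):
        raise InvalidInputError(f"delta_tep must be finite, got {delta_tep}")
    new = initial_driving + delta_tep
    percent = -delta_tep / initial_driving * 100.0
    return DrivingForceShift(new_driving=new, percent_reduction=percent, sign_reversal=new < 0.0)


def _as_mmol(side: object) -> Mapping[str, float]:
    """Coerce a composition-like object to an ion -> mmol/L mapping.

    Accepts a plain mapping (assumed mmol/L), a ``PlasmaComposition``
    (mmol/L), or any object exposing an ``ions_mmol`` mapping such as
    :class:`gilltep.water_chem.WaterComposition` (stored in umol/L,
    converted by the property).
    """
    if isinstance(side, PlasmaComposition):
        return side.concentrations
    ions_mmol = getattr(side, "ions_mmol", None)
    if ions_mmol is not None:
        return ions_mmol
    if isinstance(side, Mapping):
        return side
    raise InvalidInputError(f"cannot interpret {type(side).__name__} as an ion composition")


def _ghk_terms(
    perm: Mapping[str, float],
    water: Mapping[str, float],
    plasma: Mapping[str, float],
) -> tuple[float, float]:
    """Numerator and denominator of the GHK argument.

    Numerator:  sum_cations P_i [i]_out + sum_anions P_j [j]_in
    Denominator: sum_cations P_i [i]_in + sum_anions P_j [j]_out
    """
    num = 0.0
    den = 0.0
    for ion, p in perm.items():
        if p == 0.0:
            continue
        if not is_monovalent(ion):
            raise UnsupportedModelError(
                f"divalent ion {ion!r} has nonzero permeability; the GHK voltage "
                "equation used here is valid for monovalent ions only"
            )
        c_out = water.get(ion, 0.0)
        c_in = plasma.get(ion, 0.0)
        if valence(ion) > 0:
            num += p * c_out
            den += p * c_in
        else:
            num += p * c_in
            den += p * c_out
    return num, den


def ghk_voltage(
    permeabilities: GHKPermeabilitySet | Mapping[str, float],
    water: object,
    plasma: object,
    temperature: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Goldman-Hodgkin-Katz diffusion potential, mV (inside vs. water = 0).

    V = (RT/F) ln[(sum_cat P[c]_out + sum_an P[a]_in) /
                  (sum_cat P[c]_in  + sum_an P[a]_out)]

    Only monovalent ions are supported; a divalent ion with nonzero
    permeability raises :class:`UnsupportedModelError` rather than being
    silently dropped.  ``water`` and ``plasma`` may be plain ion->mmol/L
    mappings, a ``PlasmaComposition``, or a ``WaterComposition`` (umol/L,
    converted internally).

    With symmetric solutions on both sides the potential is exactly 0 mV
    for any permeability set — the abolition-by-isotonic-saline behaviour
    that identifies the TEP as a pure diffusion potential.
    """
    perm = (
        permeabilities.relative_permeability
        if isinstance(permeabilities, GHKPermeabilitySet)
        else dict(permeabilities)
    )
    water_m = _as_mmol(water)
    plasma_m = _as_mmol(plasma)
    num, den = _ghk_terms(perm, water_m, plasma_m)
    if num <= 0.0 or den <= 0.0:
        raise InvalidInputError(
            "GHK argument is non-positive: need at least one permeant ion with "
            f"nonzero concentration on each side (numerator={num}, denominator={den})"
        )
    slope = nernst_slope(temperature, "natural", constants)
    return slope * math.log(num / den)


def ghk_fit_permeability_ratio(
    tep: float,
    water: object,
    plasma: object,
    temperature: float,
    fixed_permeabilities: Mapping[str, float] | None = None,
    ion: str = "Na",
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Closed-form inversion of the GHK equation for one unknown permeability.

    Given the measured TEP, the two compositions and the permeabilities of
    every other ion (default: Cl- alone at the reference value 1), solve for
    the relative permeability of *ion* (default Na+, so the result is the
    P_Na/P_Cl ratio).  The GHK equation is linear in the unknown:

        exp(V F / RT) = (P_x [x]_out + a) / (P_x [x]_in + b)
        =>  P_x = (E b - a) / ([x]_out - E [x]_in),   E = exp(V F / RT)

    where ``a`` and ``b`` collect the fixed permeability-weighted terms of
    the numerator and denominator.

    Raises
    ------
    DegenerateSolutionError
        If both numerator and denominator of the solution vanish (symmetric
        solutions at 0 mV: any ratio fits).
    InfeasiblePotentialError
        If the solution is non-positive, i.e. no physical permeability of
        *ion* can produce the requested TEP.
    """
    if not is_monovalent(ion):
        raise UnsupportedModelError(f"cannot fit a GHK permeability for divalent ion {ion!r}")
    if fixed_permeabilities is None:
        fixed_permeabilities = {"Cl": 1.0}
    if ion in fixed_permeabilities:
        raise InvalidInputError(f"{ion!r} appears in the fixed permeability set")
    water_m = _as_mmol(water)
    plasma_m = _as_mmol(plasma)
    a, b = _ghk_terms(fixed_permeabilities, water_m, plasma_m)
    slope = nernst_slope(temperature, "natural", constants)
    e_fac = math.exp(tep / slope)
    if valence(ion) > 0:
        c_num = water_m.get(ion, 0.0)  # multiplies P_x in the numerator
        c_den = plasma_m.get(ion, 0.0)
    else:
        c_num = plasma_m.get(ion, 0.0)
        c_den = water_m.get(ion, 0.0)
    denom = c_num - e_fac * c_den
    numer = e_fac * b - a
    if abs(denom) < _DEGENERATE_TOL and abs(numer) < _DEGENERATE_TOL:
        raise DegenerateSolutionError(
            f"TEP {tep} mV is consistent with any permeability of {ion!r} "
            "(symmetric solutions); the ratio is under-determined"
        )
    if abs(denom) < _DEGENERATE_TOL:
        raise InfeasiblePotentialError(
            f"TEP {tep} mV cannot be produced by any finite permeability of {ion!r}"
        )
    x = numer / denom
    if x <= 0.0:
        raise InfeasiblePotentialError(
            f"TEP {tep} mV would require a non-positive permeability for {ion!r} (got {x:.6g})"
        )
    return x
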