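"""Physical constants and the ion registry shared across modules."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ConfigurationError, InvalidInputError


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic constants for Nernst/GHK arithmetic.

    Attributes
    ----------
    R : float
        Gas constant, J mol^-1 K^-1.
    F : float
        Faraday constant, C mol^-1.
    zero_celsius : float
        Additive offset from degrees Celsius to kelvin.
    """

    R: float = 8.314
    F: float = 96485.0
    zero_celsius: float = 273.15

    def kelvin(self, temperature_c: float) -> float:
        """Convert a Celsius temperature to kelvin, validating finiteness."""
        if not math.isfinite(temperature_c):
            raise InvalidInputError(f"temperature must be finite, got {temperature_c!r}")
        t_k = temperature_c + self.zero_celsius
        if t_k <= 0.0:
            raise InvalidInputError(f"temperature {temperature_c} degC is at or below absolute zero")
        return t_k


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class IonSpecies:
    """An ion identified by name with a signed integer valence."""

    name: str
    z: int

    def __post_init__(self) -> None:
        if self.z not in (-2, -1, 1, 2):
            raise InvalidInputError(f"valence must be in {{-2,-1,+1,+2}}, got {self.z}")


#: Signed valences of every ion the package knows about.  Water ion maps are
#: keyed by these bare names (no charge suffix).
ION_VALENCE: dict[str, int] = {
    "Na": +1,
    "K": +1,
    "NH4": +1,
    "H": +1,
    "Ca": +2,
    "Mg": +2,
    "Cl": -1,
    "OH": -1,
}


def valence(ion: str) -> int:
    """Look up the signed valence of *ion*, raising a configuration error if unknown."""
    try:
        return ION_VALENCE[ion]
    except KeyError:
        raise ConfigurationError(f"unknown ion {ion!r}; known ions: {sorted(ION_VALENCE)}") from None


def is_monovalent(ion: str) -> bool:
    return abs(valence(ion)) == 1
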