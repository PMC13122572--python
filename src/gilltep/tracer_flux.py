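"""Radiotracer unidirectional Na flux calculus and Q10 temperature analysis.

A fish sits in a small chamber of volume V to which a dose of 22Na tracer
has been added.  Water radioactivity ([R], cpm/L) and total water sodium
([Na], nmol/L) are sampled at the start (i) and end (f) of the flux period.
Because the tracer initially exists only in the water, its disappearance
measures the unidirectional influx:

    J_in  = ([R]_i - [R]_f) V / (SA t M)          (nmol g^-1 h^-1, >= 0)
    J_net = ([Na]_i - [Na]_f) V / (t M)           (signed; positive = uptake)
    J_out = J_net - J_in                          (<= 0 by convention)

where SA is the mean external specific activity (cpm per nmol of Na) over
the period, t the duration (h) and M the fish mass (g).  No isotope
backflux or decay correction is applied (22Na's half-life of 2.6 years
dwarfs a 1-h flux, and counting quench is assumed constant so cpm is
proportional to dpm); the bias of the no-backflux assumption is quantified
by :mod:`gilltep.synthetic_data`.

Temperature sensitivity is summarised by the conventional Q10,
``Q10 = (R2/R1)^(10/(T2-T1))``, plus a span-weighted geometric composition
that combines adjacent-interval Q10s into the full-range value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import (
    InvalidInputError,
    NegativeInfluxError,
    PositiveEffluxError,
    UndefinedQ10Error,
)

__all__ = [
    "FluxExperimentRecord",
    "FluxRates",
    "TemperatureRatePair",
    "mean_specific_activity",
    "influx",
    "net_flux",
    "efflux",
    "flux_rates",
    "q10",
    "q10_compose",
]


@dataclass(frozen=True)
class FluxExperimentRecord:
    """One fish's two-sample radiotracer flux experiment.

    Units: mass g, volume L, duration h, radioactivity cpm/L, sodium nmol/L.
    """

    fish_id: str
    mass: float
    volume: float
    duration: float
    r_initial: float
    r_final: float
    na_initial: float
    na_final: float
    temperature: float = 27.0

    def __post_init__(self) -> None:
        for label, v in (("mass", self.mass), ("volume", self.volume), ("duration", self.duration)):
            if not (v > 0.0 and math.isfinite(v)):
                raise InvalidInputError(f"{label} must be positive and finite, got {v}")
        for label, v in (("na_initial", self.na_initial), ("na_final", self.na_final)):
            if not (v > 0.0 and math.isfinite(v)):
                raise InvalidInputError(f"{label} must be positive and finite, got {v}")
        for label, v in (("r_initial", self.r_initial), ("r_final", self.r_final)):
            if not (v >= 0.0 and math.isfinite(v)):
                raise InvalidInputError(f"{label} must be >= 0 and finite, got {v}")


@dataclass(frozen=True)
class FluxRates:
    """Unidirectional and net Na flux rates, nmol g^-1 h^-1.

    The identity ``j_net == j_in + j_out`` and the sign conventions
    (influx >= 0, efflux <= 0) are enforced at construction.
    """

    j_in: float
    j_out: float
    j_net: float

    def __post_init__(self) -> None:
        if self.j_in < 0.0:
            raise InvalidInputError(f"j_in must be >= 0, got {self.j_in}")
        if self.j_out > 0.0:
            raise PositiveEffluxError(f"j_out must be <= 0, got {self.j_out}")
        if not math.isclose(self.j_net, self.j_in + self.j_out, rel_tol=0.0, abs_tol=1e-9):
            raise InvalidInputError(
                f"flux identity violated: j_net={self.j_net} != j_in+j_out={self.j_in + self.j_out}"
            )


@dataclass(frozen=True)
class TemperatureRatePair:
    """The same rate process measured at two temperatures (degC)."""

    r1: float
    r2: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.t1 == self.t2:
            raise InvalidInputError("the two temperatures must differ")
        if self.r1 == 0.0 or self.r2 == 0.0 or (self.r1 > 0.0) != (self.r2 > 0.0):
            raise UndefinedQ10Error(
                f"Q10 requires two nonzero rates of the same sign, got {self.r1} and {self.r2}"
            )


def mean_specific_activity(record: FluxExperimentRecord) -> float:
    """Mean external specific activity over the flux period, cpm/nmol.

    The arithmetic mean of the start and end specific activities R/[Na].
    (Taking instead the ratio of mean R to mean [Na] differs by well under
    1% at typical drawdowns but is not symmetric under time reversal.)
    """
    sa_i = record.r_initial / record.na_initial
    sa_f = record.r_final / record.na_final
    return 0.5 * (sa_i + sa_f)


def influx(record: FluxExperimentRecord) -> float:
    """Unidirectional Na influx J_in, nmol g^-1 h^-1 (nonnegative)."""
    if record.r_final > record.r_initial:
        raise NegativeInfluxError(
            f"water radioactivity rose ({record.r_initial} -> {record.r_final} cpm/L) "
            "during the flux period; check for contamination or tracer backflux"
        )
    sa = mean_specific_activity(record)
    if sa <= 0.0:
        raise InvalidInputError("mean specific activity must be positive to estimate influx")
    return (record.r_initial - record.r_final) * record.volume / (sa * record.duration * record.mass)


def net_flux(record: FluxExperimentRecord) -> float:
    """Net Na flux J_net, nmol g^-1 h^-1 (positive = net uptake)."""
    return (record.na_initial - record.na_final) * record.volume / (record.duration * record.mass)


def efflux(j_net: float, j_in: float) -> float:
    """Unidirectional Na efflux J_out = J_net - J_in, nmol g^-1 h^-1 (<= 0)."""
    if j_in < 0.0:
        raise InvalidInputError(f"j_in must be >= 0, got {j_in}")
    j_out = j_net - j_in
    if j_out > 0.0:
        raise PositiveEffluxError(
            f"computed efflux {j_out} > 0 violates the unidirectional sign convention "
            f"(j_net={j_net}, j_in={j_in})"
        )
    return j_out


def flux_rates(record: FluxExperimentRecord) -> FluxRates:
    """All three flux rates for one record; the Eq.-identity holds by construction."""
    j_in = influx(record)
    j_net = net_flux(record)
    j_out = efflux(j_net, j_in)
    return FluxRates(j_in=j_in, j_out=j_out, j_net=j_net)


def q10(pair: TemperatureRatePair) -> float:
    """Temperature coefficient Q10 = (R2/R1)^(10/(T2-T1)).

    Defined for two nonzero rates of the same sign (the ratio of signed
    rates is then positive, so negative efflux rates are handled
    naturally).  Equals 1 iff the rates are equal.
    """
    return (pair.r2 / pair.r1) ** (10.0 / (pair.t2 - pair.t1))


def q10_compose(
    q_ab: float,
    q_bc: float,
    t_a: float = 21.0,
    t_b: float = 27.0,
    t_c: float = 33.0,
) -> float:
    """Combine Q10s over adjacent intervals [t_a,t_b] and [t_b,t_c].

    Under log-linear rate-temperature scaling within each interval the
    full-range coefficient is the span-weighted geometric composition

        Q10[a,c] = (q_ab^(t_b-t_a) * q_bc^(t_c-t_b))^(1/(t_c-t_a)),

    which for equal spans reduces to the geometric mean.  Exactly
    consistent with :func:`q10` applied to the end points of a piecewise
    log-linear rate curve, and associative over adjacent intervals.
    """
    if not (t_a < t_b < t_c):
        raise InvalidInputError(f"temperatures must be strictly increasing, got {t_a}, {t_b}, {t_c}")
    for label, q in (("q_ab", q_ab), ("q_bc", q_bc)):
        if not (q > 0.0 and math.isfinite(q)):
            raise InvalidInputError(f"{label} must be positive and finite, got {q}")
    log_q = ((t_b - t_a) * math.log(q_ab) + (t_c - t_b) * math.log(q_bc)) / (t_c - t_a)
    return math.exp(log_q)
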