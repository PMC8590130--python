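"""Cosinor parameterization algebra.

The single-component cosinor model describes a periodic signal as

    Y(t) = M + A * cos(2*pi*t/tau + phi) + e(t)

with MESOR ``M`` (rhythm-adjusted mean), amplitude ``A`` (half the
peak-to-trough extent) and acrophase ``phi`` (phase angle locating the
peak).  The model is non-linear in ``A`` and ``phi`` but becomes linear
after recoding time into the unit-circle regressors

    x = cos(2*pi*t/tau),   z = sin(2*pi*t/tau)

so that ``Y = M + beta*x + gamma*z`` with ``beta = A*cos(phi)`` and
``gamma = -A*sin(phi)``.  This module implements that algebra: the time
recoding, the exact linear<->nonlinear inverse maps, and circular
arithmetic for acrophase differences.

Conventions
-----------
Acrophase is reported in ``(-2*pi, 0]`` so that the peak time
``-phi * tau / (2*pi)`` is nonnegative and below one period.  Acrophase
*differences* are wrapped to ``(-pi, pi]``, the minimal circular
difference, with the boundary tie resolved to ``+pi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = [
    "SpecificationError",
    "RhythmRegressors",
    "LinearCoefficients",
    "CosinorParams",
    "recode_time",
    "linear_to_cosinor",
    "cosinor_to_linear",
    "wrap_phase_difference",
    "wrap_time_difference",
    "acrophase_to_peak_time",
]


class SpecificationError(ValueError):
    """An invalid model, dataset or parameter specification."""


@dataclass(frozen=True)
class RhythmRegressors:
    """Unit-circle regressors for one time point: x^2 + z^2 = 1."""

    x: float
    z: float
    t: float
    period: float


@dataclass(frozen=True)
class LinearCoefficients:
    """Linear-scale cosinor coefficients (M, beta, gamma)."""

    mesor: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.mesor, self.beta, self.gamma])):
            raise SpecificationError("linear coefficients must be finite")


@dataclass(frozen=True)
class CosinorParams:
    """Nonlinear cosinor triple (MESOR, amplitude, acrophase).

    ``acrophase`` lies in ``(-2*pi, 0]``; ``peak_time`` is the clock time
    of the fitted maximum within one period, in hours.  ``degenerate``
    marks a zero amplitude, for which the acrophase is undefined and set
    to 0 by convention.
    """

    mesor: float
    amplitude: float
    acrophase: float
    peak_time: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise SpecificationError("amplitude must be nonnegative")


def _check_period(period: float) -> None:
    if not np.isfinite(period) or period <= 0:
        raise SpecificationError(f"period must be a positive number, got {period!r}")


def recode_time(t: float, period: float = 24.0) -> RhythmRegressors:
    """Recode a time point into the linearizing regressors (x, z).

    The recoding is periodic: times outside ``[0, period)`` wrap around.
    """
    _check_period(period)
    t = float(t)
    if not np.isfinite(t):
        raise SpecificationError("time must be finite")
    angle = TWO_PI * t / period
    return RhythmRegressors(x=math.cos(angle), z=math.sin(angle), t=t, period=period)


def recode_time_array(t, period: float = 24.0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (x, z) recoding; returns two arrays."""
    _check_period(period)
    t = np.asarray(t, dtype=float)
    angle = TWO_PI * t / period
    return np.cos(angle), np.sin(angle)


def acrophase_to_peak_time(acrophase: float, period: float) -> float:
    """Clock time of the fitted peak: (-phi * tau / 2pi) mod tau."""
    _check_period(period)
    return float((-acrophase * period / TWO_PI) % period)


def linear_to_cosinor(
    c: LinearCoefficients, period: float = 24.0
) -> CosinorParams:
    """Invert the linearization: (M, beta, gamma) -> (M, A, phi).

    ``A = sqrt(beta^2 + gamma^2)``; ``phi`` is the unique angle in
    ``(-2*pi, 0]`` with ``beta = A cos(phi)`` and ``gamma = -A sin(phi)``.
    A zero amplitude leaves the acrophase undefined: it is set to 0 and
    the result is flagged degenerate.
    """
    _check_period(period)
    amplitude = math.hypot(c.beta, c.gamma)
    if amplitude == 0.0:
        return CosinorParams(
            mesor=c.mesor, amplitude=0.0, acrophase=0.0, peak_time=0.0, degenerate=True
        )
    phi = math.atan2(-c.gamma, c.beta)
    if phi > 0.0:
        phi -= TWO_PI
    return CosinorParams(
        mesor=c.mesor,
        amplitude=amplitude,
        acrophase=phi,
        peak_time=acrophase_to_peak_time(phi, period),
    )


def cosinor_to_linear(p: CosinorParams) -> LinearCoefficients:
    """Forward map (M, A, phi) -> (M, beta, gamma); exact inverse of
    :func:`linear_to_cosinor` for positive amplitude."""
    if p.amplitude < 0:
        raise SpecificationError("amplitude must be nonnegative")
    return LinearCoefficients(
        mesor=p.mesor,
        beta=p.amplitude * math.cos(p.acrophase),
        gamma=-p.amplitude * math.sin(p.acrophase),
    )


def wrap_phase_difference(phi1: float, phi2: float) -> float:
    """Minimal circular difference phi1 - phi2, wrapped to (-pi, pi].

    The boundary case (difference congruent to pi) maps to +pi.
    """
    d = (float(phi1) - float(phi2)) % TWO_PI
    if d > math.pi:
        d -= TWO_PI
    return d


def wrap_time_difference(dphi: float, period: float) -> float:
    """Peak-time difference in hours for a wrapped phase difference.

    A phase difference ``dphi`` (radians) corresponds to a peak-time
    shift of ``-dphi * tau / (2*pi)`` hours, wrapped to
    ``(-tau/2, tau/2]``.
    """
    _check_period(period)
    d = (-float(dphi) * period / TWO_PI) % period
    if d > period / 2.0:
        d -= period
    return d
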