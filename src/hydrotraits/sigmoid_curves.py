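"""Exponential-sigmoid percent-response model for vulnerability and closure curves.

The model is

    percent(P) = 100 / (1 + exp(a * (P - p50)))

with pressure ``P`` in MPa (negative), slope parameter ``a`` in MPa^-1
(positive) and ``p50`` the pressure at 50% response. The same model serves
percentage loss of hydraulic conductivity (PLC) against xylem pressure and
percentage stomatal conductance against leaf water potential; only the
interpretation of the 12/50/88% thresholds differs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from hydrotraits.errors import (
    FitError,
    InsufficientDataError,
    InvalidInputError,
    NonIdentifiableError,
)

logger = logging.getLogger(__name__)

#: ln(100/12 - 1) = ln(22/3): half-width of the 12-88% band for a = 1.
LN_22_3 = math.log(22.0 / 3.0)

#: Minimum spread of observed percents for an identifiable fit (percent units).
MIN_PERCENT_RANGE = 30.0

MIN_POINTS = 4


@dataclass(frozen=True)
class ResponsePoint:
    """One (pressure, percent-response) observation.

    Attributes
    ----------
    pressure : float
        Water potential in MPa; finite and non-positive.
    percent : float
        Response level in percent; nominally 0-100 but noisy values may
        slightly exceed the range and are retained unclipped.
    """

    pressure: float
    percent: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pressure) or self.pressure > 0:
            raise InvalidInputError(
                f"pressure must be finite and non-positive (MPa), got {self.pressure!r}; "
                "pressures follow the negative-MPa convention"
            )
        if not math.isfinite(self.percent):
            raise InvalidInputError(f"percent must be finite, got {self.percent!r}")


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted sigmoid parameters with least-squares diagnostics."""

    a: float
    p50: float
    residual_sse: float = 0.0
    n_points: int = MIN_POINTS

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and self.a > 0):
            raise InvalidInputError(f"slope a must be finite and > 0, got {self.a!r}")
        if not (math.isfinite(self.p50) and self.p50 < 0):
            raise InvalidInputError(f"p50 must be finite and < 0, got {self.p50!r}")
        if self.residual_sse < 0:
            raise InvalidInputError("residual_sse must be >= 0")
        if self.n_points < MIN_POINTS:
            raise InvalidInputError(f"n_points must be >= {MIN_POINTS}")


@dataclass(frozen=True)
class Thresholds:
    """12/50/88% response pressures, ordered least to most negative."""

    p12: float
    p50: float
    p88: float

    def __post_init__(self) -> None:
        if not (self.p12 > self.p50 > self.p88):
            raise InvalidInputError(
                f"expected p12 > p50 > p88, got {self.p12}, {self.p50}, {self.p88}"
            )


def percent_at(fit: SigmoidFit, pressure: float) -> float:
    """Evaluate the sigmoid response at ``pressure`` (MPa).

    Strictly decreasing in pressure (increasing as pressure becomes more
    negative) and bounded in (0, 100).
    """
    if not math.isfinite(pressure):
        raise InvalidInputError(f"pressure must be finite, got {pressure!r}")
    return 100.0 / (1.0 + math.exp(fit.a * (pressure - fit.p50)))


def pressure_at_percent(fit: SigmoidFit, level: float) -> float:
    """Invert the sigmoid: pressure (MPa) at which the response equals ``level`` %."""
    if not (0.0 < level < 100.0):
        raise InvalidInputError(f"level must lie strictly in (0, 100), got {level!r}")
    return fit.p50 + math.log(100.0 / level - 1.0) / fit.a


def thresholds_of(fit: SigmoidFit) -> Thresholds:
    """12/50/88% pressures of a fit.

    The logistic is symmetric, so p12 - p50 == p50 - p88 == ln(22/3)/a.
    """
    half_width = LN_22_3 / fit.a
    return Thresholds(p12=fit.p50 + half_width, p50=fit.p50, p88=fit.p50 - half_width)


def _model(params: np.ndarray, pressures: np.ndarray) -> np.ndarray:
    a, p50 = params
    return 100.0 / (1.0 + np.exp(np.clip(a * (pressures - p50), -500, 500)))


def _initial_guess(pressures: np.ndarray, percents: np.ndarray) -> tuple[float, float]:
    # p50 start: pressure of the observation closest to the 50% level.
    idx = int(np.argmin(np.abs(percents - 50.0)))
    return 1.0, float(pressures[idx])


def fit_sigmoid(
    points: Iterable[ResponsePoint] | Sequence[tuple[float, float]],
    init: tuple[float, float] | None = None,
) -> SigmoidFit:
    """Least-squares fit of the sigmoid to (pressure, percent) observations.

    Parameters
    ----------
    points
        ``ResponsePoint`` objects or bare (pressure, percent) pairs; at least
        four, spanning both sides of the 50% level. Percents outside [0, 100]
        are retained unclipped (clipping would bias the slope).
    init
        Optional (a, p50) starting values; by default a = 1 and p50 at the
        observation nearest 50%.

    Raises
    ------
    InsufficientDataError
        Fewer than four points.
    NonIdentifiableError
        Percent spread < 30 units, all percents on one side of 50%, or zero
        pressure spread.
    FitError
        The optimiser failed from the default and three perturbed starts.
    """
    pts = [p if isinstance(p, ResponsePoint) else ResponsePoint(*p) for p in points]
    if len(pts) < MIN_POINTS:
        raise InsufficientDataError(
            f"need at least {MIN_POINTS} points to fit a sigmoid, got {len(pts)}"
        )
    pressures = np.array([p.pressure for p in pts], dtype=float)
    percents = np.array([p.percent for p in pts], dtype=float)

    if np.ptp(percents) < MIN_PERCENT_RANGE:
        raise NonIdentifiableError(
            f"percent spread {np.ptp(percents):.1f} < {MIN_PERCENT_RANGE:.0f} units: "
            "response range too narrow to identify (a, p50)"
        )
    if np.all(percents >= 50.0) or np.all(percents <= 50.0):
        raise NonIdentifiableError(
            "all percents lie on one side of 50%: p50 is not bracketed by the data"
        )
    if np.ptp(pressures) == 0.0:
        raise NonIdentifiableError("zero pressure spread: slope is not identifiable")

    if init is None:
        starts = [_initial_guess(pressures, percents)]
    else:
        starts = [(float(init[0]), float(init[1]))]
    # Perturbed retries (deterministic) in case the first start stalls.
    a0, p0 = starts[0]
    spread = float(np.ptp(pressures))
    starts += [
        (a0 * 2.0, p0 - 0.25 * spread),
        (a0 * 0.5, p0 + 0.25 * spread),
        (a0 * 3.0, float(np.median(pressures))),
    ]

    best: SigmoidFit | None = None
    best_sse = math.inf
    for a_start, p_start in starts:
        try:
            sol = least_squares(
                lambda q: _model(q, pressures) - percents,
                x0=[max(a_start, 1e-3), min(p_start, -1e-6)],
                bounds=([1e-6, -np.inf], [np.inf, 0.0]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:  # pragma: no cover - scipy raising is itself a failed start
            continue
        if not sol.success:
            continue
        a_hat, p50_hat = sol.x
        if not (a_hat > 0 and p50_hat < 0):
            continue
        sse = float(np.sum(sol.fun**2))
        if sse < best_sse:
            best_sse = sse
            best = SigmoidFit(
                a=float(a_hat), p50=float(p50_hat), residual_sse=sse, n_points=len(pts)
            )
        if best is not None and init is None:
            break  # the default start converged; no need for retries
    if best is None:
        raise FitError("sigmoid fit failed to converge from 4 starting points")
    return best
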