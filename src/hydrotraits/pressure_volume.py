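"""Pressure-volume analysis of leaf dehydration series.

Each leaf yields a series of (water saturation deficit, leaf water potential)
observations. Plotting 1/psi against WSD separates the curve into a curved
turgescent section (turgor still positive) and a linear osmotic section.
The osmotic line extrapolated to WSD = 0 gives the osmotic potential at full
saturation (psi_osat = 1/intercept); the intersection of the turgescent
parabola with the osmotic line locates the turgor loss point (psi_tlp); the
quadratic coefficient of the parabola is the wall-elasticity index a_ela
(larger = narrower parabola = stiffer walls).

Segmentation: the osmotic segment is the longest high-WSD suffix whose
ordinary-least-squares line fits to within the series' own noise scale
(estimated from the extreme tail, which is always osmotic). A quadratic is
then fitted through the turgescent points adjacent to the boundary; fitting
it locally rather than over the whole turgescent section keeps the
intersection accurate, because 1/psi diverges hyperbolically toward full
saturation and a single global parabola systematically undershoots the
line near the turgor loss point. When the parabola misses the line by a
hair (negative discriminant), the point of closest approach is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from hydrotraits.errors import (
    FitError,
    InsufficientDataError,
    InvalidInputError,
    NoTurgorLossPointError,
)

logger = logging.getLogger(__name__)

MIN_POINTS = 6
MIN_SEGMENT = 3

#: Line mean-squared residual may exceed the tail noise estimate by this
#: factor before a split is rejected as contaminated by turgescent points.
LINE_TOLERANCE_FACTOR = 2.0

#: Number of turgescent points (nearest the boundary) the parabola is
#: fitted through.
PARABOLA_WINDOW = 3

#: Number of trailing points used to estimate the 1/psi noise scale.
NOISE_TAIL = 8


@dataclass(frozen=True)
class LeafMasses:
    """Turgid, fresh and oven-dry mass of one leaf (g)."""

    tw: float
    fw: float
    dw: float

    def __post_init__(self) -> None:
        if not (self.dw > 0):
            raise InvalidInputError(f"dry mass must be > 0, got {self.dw!r}")
        if self.fw > self.tw:
            raise InvalidInputError(
                f"fresh mass {self.fw} exceeds turgid mass {self.tw}: mass ordering violated"
            )
        if self.dw > self.fw:
            raise InvalidInputError(
                f"dry mass {self.dw} exceeds fresh mass {self.fw}: mass ordering violated"
            )


@dataclass(frozen=True)
class PVPoint:
    """One (WSD, psi) observation; inv_psi is derived on construction."""

    wsd: float
    psi: float
    inv_psi: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.wsd < 1.0):
            raise InvalidInputError(f"wsd must lie in [0, 1), got {self.wsd!r}")
        if not (math.isfinite(self.psi) and self.psi < 0):
            raise InvalidInputError(f"psi must be finite and < 0 MPa, got {self.psi!r}")
        object.__setattr__(self, "inv_psi", 1.0 / self.psi)


@dataclass(frozen=True)
class PVResult:
    """Derived water-relations parameters for one leaf.

    ``parab_coeffs`` are (c0, c1, c2) for 1/psi = c0 + c1*WSD + c2*WSD^2 on
    the turgescent boundary window; ``a_ela`` = |c2|.
    """

    psi_osat: float
    psi_tlp: float
    a_ela: float
    split_wsd: float
    line_slope: float
    line_intercept: float
    parab_coeffs: tuple[float, float, float]
    residual_sse: float = 0.0
    n_points: int = MIN_POINTS

    def __post_init__(self) -> None:
        if not (self.psi_osat < 0):
            raise InvalidInputError(f"psi_osat must be < 0, got {self.psi_osat!r}")
        if self.psi_tlp > self.psi_osat:
            raise FitError(
                f"psi_tlp ({self.psi_tlp:.3f}) less negative than psi_osat "
                f"({self.psi_osat:.3f}): fitting failure"
            )
        if not (self.a_ela > 0):
            raise InvalidInputError(f"a_ela must be > 0, got {self.a_ela!r}")
        if not (0.0 < self.split_wsd < 1.0):
            raise InvalidInputError(f"split_wsd must lie in (0, 1), got {self.split_wsd!r}")


def compute_wsd(masses: LeafMasses) -> float:
    """Water saturation deficit (TW - FW)/(TW - DW), i.e. 1 - relative water content."""
    denom = masses.tw - masses.dw
    if denom <= 0:
        raise InvalidInputError(
            f"turgid mass {masses.tw} must exceed dry mass {masses.dw} "
            "(degenerate leaf: no water content)"
        )
    return (masses.tw - masses.fw) / denom


def _line_fit(w: np.ndarray, iv: np.ndarray) -> tuple[np.ndarray, float]:
    coeffs = npoly.polyfit(w, iv, 1)
    mse = float(np.sum((npoly.polyval(w, coeffs) - iv) ** 2)) / max(len(w) - 2, 1)
    return coeffs, mse


def _choose_split(w: np.ndarray, iv: np.ndarray, factor: float, tail: int) -> int:
    """Smallest split index whose osmotic-line fit is noise-consistent."""
    n = len(w)
    tail = max(MIN_SEGMENT, min(tail, n - MIN_SEGMENT))
    _, tail_mse = _line_fit(w[-tail:], iv[-tail:])
    sigma2 = max(tail_mse, 1e-16)
    fallback, fallback_mse = None, math.inf
    for split in range(MIN_SEGMENT, n - MIN_SEGMENT + 1):
        _, mse = _line_fit(w[split:], iv[split:])
        if mse <= factor * sigma2:
            return split
        if mse < fallback_mse:
            fallback, fallback_mse = split, mse
    assert fallback is not None
    logger.warning(
        "fit_pv: no split passes the line-straightness tolerance; falling back to "
        "the split with the lowest line mean-squared residual (%.3g)",
        fallback_mse,
    )
    return fallback


def fit_pv(
    points: Iterable[PVPoint] | Sequence[tuple[float, float]],
    *,
    line_tolerance_factor: float = LINE_TOLERANCE_FACTOR,
    parabola_window: int = PARABOLA_WINDOW,
) -> PVResult:
    """Fit the two-segment pressure-volume model to one leaf's series.

    Parameters
    ----------
    points
        ``PVPoint`` objects or bare (wsd, psi) pairs; at least six, covering
        both segments.
    line_tolerance_factor
        How far (multiplicatively) the osmotic line's mean-squared residual
        may exceed the tail noise estimate before the candidate split is
        rejected.
    parabola_window
        Number of turgescent points adjacent to the boundary used for the
        quadratic (minimum 3).

    Raises
    ------
    InsufficientDataError
        Fewer than six points.
    NoTurgorLossPointError
        Turgescent segment degenerates to a line (pure osmotic series) or
        the parabola/line system has no admissible solution in the observed
        WSD range.
    FitError
        Osmotic line with non-negative intercept or non-positive slope, or
        a turgor loss point at a less negative potential than psi_osat.
    """
    pts = [p if isinstance(p, PVPoint) else PVPoint(*p) for p in points]
    if len(pts) < MIN_POINTS:
        raise InsufficientDataError(
            f"need at least {MIN_POINTS} points for a PV fit, got {len(pts)}"
        )
    if parabola_window < MIN_SEGMENT:
        raise InvalidInputError(f"parabola_window must be >= {MIN_SEGMENT}")
    pts = sorted(pts, key=lambda p: p.wsd)
    wsd = np.array([p.wsd for p in pts])
    inv_psi = np.array([p.inv_psi for p in pts])
    lo, hi = float(wsd[0]), float(wsd[-1])

    split = _choose_split(wsd, inv_psi, line_tolerance_factor, NOISE_TAIL)
    line, line_mse = _line_fit(wsd[split:], inv_psi[split:])
    intercept, slope = float(line[0]), float(line[1])
    if intercept >= 0:
        raise FitError(
            f"osmotic line intercept {intercept:.4f} is non-negative: cannot yield psi_osat < 0"
        )
    if slope <= 0:
        raise FitError(
            f"osmotic line slope {slope:.4f} is non-positive in (WSD, 1/psi) space: "
            "1/psi must rise toward 0 during dehydration"
        )
    psi_osat = 1.0 / intercept

    pw = wsd[:split][-parabola_window:]
    pi = inv_psi[:split][-parabola_window:]
    parab = npoly.polyfit(pw, pi, 2)
    c0, c1, c2 = (float(c) for c in parab)
    if abs(c2) < 1e-12:
        raise NoTurgorLossPointError(
            "turgescent segment is indistinguishable from a line: the series has "
            "no curved (turgescent) section, so no turgor loss point exists"
        )
    parab_sse = float(np.sum((npoly.polyval(pw, parab) - pi) ** 2))

    # Parabola - line: c2 w^2 + (c1 - slope) w + (c0 - intercept) = 0
    A, B, C = c2, c1 - slope, c0 - intercept
    disc = B * B - 4.0 * A * C
    boundary = float(wsd[split - 1] + wsd[split]) / 2.0
    if disc >= 0:
        r1 = (-B - math.sqrt(disc)) / (2.0 * A)
        r2 = (-B + math.sqrt(disc)) / (2.0 * A)
        inside = [r for r in (r1, r2) if lo <= r <= hi]
        if not inside:
            raise NoTurgorLossPointError(
                f"parabola/line intersections ({r1:.3f}, {r2:.3f}) fall outside the "
                f"observed WSD range [{lo:.3f}, {hi:.3f}]"
            )
        # If two admissible roots, take the one nearest the segment boundary.
        w_tlp = min(inside, key=lambda r: abs(r - boundary))
    else:
        # Near-tangent geometry: the parabola stops just short of the line.
        # The closest-approach abscissa is the natural intersection estimate.
        w_tlp = -B / (2.0 * A)
        gap = abs(A * w_tlp * w_tlp + B * w_tlp + C)
        if not (lo <= w_tlp <= hi):
            raise NoTurgorLossPointError(
                f"parabola misses the osmotic line; closest approach at WSD "
                f"{w_tlp:.3f} lies outside [{lo:.3f}, {hi:.3f}]"
            )
        if gap > 0.25 * float(np.ptp(inv_psi)):
            raise NoTurgorLossPointError(
                f"parabola misses the osmotic line by {gap:.3g} MPa^-1 "
                "(more than a quarter of the observed 1/psi range)"
            )
        logger.debug("fit_pv: tangent-gap intersection, gap %.3g at WSD %.3f", gap, w_tlp)
    inv_psi_tlp = intercept + slope * w_tlp
    if inv_psi_tlp >= 0:
        raise NoTurgorLossPointError(
            f"osmotic line evaluates to non-negative 1/psi at WSD {w_tlp:.3f}"
        )

    return PVResult(
        psi_osat=psi_osat,
        psi_tlp=1.0 / inv_psi_tlp,
        a_ela=abs(c2),
        split_wsd=boundary,
        line_slope=slope,
        line_intercept=intercept,
        parab_coeffs=(c0, c1, c2),
        residual_sse=line_mse * max(len(pts) - split - 2, 1) + parab_sse,
        n_points=len(pts),
    )


def summarize_pv(results: Sequence[PVResult]) -> dict[str, tuple[float, float | None]]:
    """Mean and standard error of psi_osat, psi_tlp and a_ela across leaves.

    With a single leaf the SE is ``None`` (undefined) and a warning is logged.
    """
    if not results:
        raise InsufficientDataError("no PV results to summarize")
    out: dict[str, tuple[float, float | None]] = {}
    for name in ("psi_osat", "psi_tlp", "a_ela"):
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        if len(vals) < 2:
            logger.warning("summarize_pv: single leaf, SE undefined for %s", name)
            out[name] = (float(vals[0]), None)
        else:
            out[name] = (float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(len(vals))))
    return out
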