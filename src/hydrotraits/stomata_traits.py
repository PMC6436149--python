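"""Stomatal operating traits and dehydration-threshold bookkeeping.

Closure analysis reuses the shared sigmoid: percent stomatal conductance
(relative to the series' own maximum) against leaf water potential, with the
potential at 12% g_s taken as full closure and at 88% g_s as closure onset.
Operating extremes (g_smax, psi_lmin) are means of the n most extreme values
of a measurement campaign. Safety margins are signed differences between
dehydration thresholds; a negative margin means the first event occurs at a
more negative potential, i.e. after the second during dehydration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from hydrotraits.anatomy import hierarchical_mean
from hydrotraits.errors import InsufficientDataError, InvalidInputError
from hydrotraits.sigmoid_curves import (
    ResponsePoint,
    SigmoidFit,
    fit_sigmoid,
    pressure_at_percent,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GasExchangePoint:
    """One paired (leaf water potential, stomatal conductance) observation."""

    psi_l: float
    gs: float
    time: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.psi_l) and self.psi_l < 0):
            raise InvalidInputError(f"psi_l must be finite and < 0 MPa, got {self.psi_l!r}")
        if not (math.isfinite(self.gs) and self.gs >= 0):
            raise InvalidInputError(f"gs must be finite and >= 0, got {self.gs!r}")


@dataclass(frozen=True)
class StomatalAnatomy:
    """Per-leaf stomatal density (mm^-2) and pore length (um)."""

    sd: float
    pore_length: float

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise InvalidInputError(f"stomatal density must be > 0, got {self.sd!r}")
        if not (self.pore_length > 0):
            raise InvalidInputError(f"pore length must be > 0, got {self.pore_length!r}")


def percent_gs(series: Sequence[GasExchangePoint]) -> list[ResponsePoint]:
    """Normalise a g_s series by its own maximum into (psi, percent) points.

    Exactly one point reaches 100% (the maximum); the output feeds
    ``fit_sigmoid``, after which psi_sc = pressure_at_percent(fit, 12) and
    the closure onset = pressure_at_percent(fit, 88).
    """
    if not series:
        raise InsufficientDataError("empty gas-exchange series")
    gs = np.array([p.gs for p in series], dtype=float)
    gs_max = float(gs.max())
    if gs_max == 0:
        raise InvalidInputError("all g_s values are zero: percent g_s undefined")
    return [
        ResponsePoint(pressure=p.psi_l, percent=100.0 * p.gs / gs_max) for p in series
    ]


@dataclass(frozen=True)
class ClosureThresholds:
    """Water potentials at the onset of closure (88% g_s), half closure
    (50% g_s) and full closure (12% g_s), with the underlying fit."""

    psi_onset: float
    psi_50: float
    psi_sc: float
    fit: SigmoidFit

    def __post_init__(self) -> None:
        if not (self.psi_onset > self.psi_50 > self.psi_sc):
            raise InvalidInputError(
                "closure thresholds must run onset > psi_50 > psi_sc "
                f"(got {self.psi_onset}, {self.psi_50}, {self.psi_sc})"
            )


def closure_thresholds(series: Sequence[GasExchangePoint]) -> ClosureThresholds:
    """Fit the shared sigmoid to a dehydration g_s course and invert it at
    the conventional conductance levels.

    Percent conductance falls during dehydration while the shared response
    model rises, so the fit is performed on percent *closure*
    (100 - percent g_s); the water potential at L% conductance is then the
    pressure at (100 - L)% response. psi_sc (12% g_s) therefore comes out
    more negative than psi_50, matching the closure-after-half-loss ordering
    seen in dehydrating leaves.
    """
    pts = percent_gs(series)
    fit = fit_sigmoid(
        [ResponsePoint(p.pressure, 100.0 - p.percent) for p in pts]
    )
    return ClosureThresholds(
        psi_onset=pressure_at_percent(fit, 100.0 - 88.0),
        psi_50=fit.p50,
        psi_sc=pressure_at_percent(fit, 100.0 - 12.0),
        fit=fit,
    )


def extreme_mean(values: Sequence[float], n: int, side: str = "highest") -> float:
    """Mean of the ``n`` most extreme values on the stated side.

    With fewer than ``n`` values, warns and uses all of them.
    """
    if side not in ("highest", "lowest"):
        raise InvalidInputError(f"side must be 'highest' or 'lowest', got {side!r}")
    if len(values) == 0:
        raise InsufficientDataError("empty value list")
    if not (n > 0):
        raise InvalidInputError(f"n must be > 0, got {n!r}")
    vals = np.sort(np.asarray(values, dtype=float))
    if len(vals) < n:
        logger.warning(
            "extreme_mean: only %d values for n=%d; using all", len(vals), n
        )
        n = len(vals)
    chosen = vals[-n:] if side == "highest" else vals[:n]
    return float(chosen.mean())


def safety_margin(threshold_a: float, threshold_b: float) -> float:
    """Signed margin a - b between two dehydration thresholds (MPa, both < 0).

    Positive: a occurs at less negative potential, i.e. before b during
    dehydration. Negative margins flag the risky ordering (e.g. stomatal
    closure only after embolism onset).
    """
    for name, v in (("threshold_a", threshold_a), ("threshold_b", threshold_b)):
        if not (math.isfinite(v) and v < 0):
            raise InvalidInputError(f"{name} must be finite and < 0 MPa, got {v!r}")
    return threshold_a - threshold_b


def sequence_thresholds(
    thresholds: Mapping[str, float] | Sequence[tuple[str, float]],
) -> list[tuple[str, float]]:
    """Order named thresholds from least to most negative potential.

    The ordering is an output, not an assumption: it reconstructs the
    sequence of events during dehydration. Ties keep input order (stable
    sort); a single threshold is returned as-is.
    """
    items = list(thresholds.items()) if isinstance(thresholds, Mapping) else list(thresholds)
    if not items:
        raise InsufficientDataError("no thresholds to sequence")
    for name, v in items:
        if not (math.isfinite(v) and v < 0):
            raise InvalidInputError(f"threshold {name!r} must be finite and < 0, got {v!r}")
    return sorted(items, key=lambda kv: -kv[1])


def stomatal_density(count: int, area_mm2: float) -> float:
    """Stomata per mm^2 on one counted region."""
    if not (area_mm2 > 0):
        raise InvalidInputError(f"counting area must be > 0 mm^2, got {area_mm2!r}")
    if count < 0:
        raise InvalidInputError(f"count must be >= 0, got {count!r}")
    return count / area_mm2


def stomatal_anatomy_summary(
    densities_per_leaf: Mapping[str, Sequence[float]],
    pore_lengths_per_leaf: Mapping[str, Sequence[float]],
) -> dict[str, tuple[float, float | None]]:
    """Group summary of stomatal density and pore length.

    Both traits are averaged per leaf first and then across leaves
    (hierarchical mean), mirroring the per-sample-first convention used for
    xylem anatomy.
    """
    if not densities_per_leaf or not pore_lengths_per_leaf:
        raise InsufficientDataError("empty leaf set")
    return {
        "sd": hierarchical_mean(densities_per_leaf),
        "pore_length": hierarchical_mean(pore_lengths_per_leaf),
    }
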