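"""Conduit- and pit-level anatomical indices.

Diameters are circular-equivalent (d = 2*sqrt(A/pi)) when derived from lumen
areas. The hydraulically weighted diameter sum(d^5)/sum(d^4) up-weights wide
conduits, which dominate flow. Group summaries average per sample first and
then across samples, so samples with many conduits do not dominate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from hydrotraits.errors import InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConduitSet:
    """Conduit measurements from one transverse section.

    Either ``lumen_areas`` (um^2) or ``diameters`` (um) must be given;
    diameters are derived from areas when areas are supplied. ``wall_pairs``
    are (double wall thickness t, conduit diameter b) pairs in um.
    """

    sample_id: str
    lumen_areas: tuple[float, ...] | None = None
    diameters: tuple[float, ...] = ()
    wall_pairs: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.lumen_areas is not None:
            areas = tuple(float(a) for a in self.lumen_areas)
            if any(a <= 0 for a in areas):
                raise InvalidInputError("lumen areas must be > 0")
            object.__setattr__(self, "lumen_areas", areas)
            object.__setattr__(
                self, "diameters", tuple(diameter_from_area(a) for a in areas)
            )
        else:
            diams = tuple(float(d) for d in self.diameters)
            if any(d <= 0 for d in diams):
                raise InvalidInputError("diameters must be > 0")
            object.__setattr__(self, "diameters", diams)
        if not self.diameters:
            raise InsufficientDataError(
                f"conduit set {self.sample_id!r} has no diameters"
            )
        for t, b in self.wall_pairs:
            if t <= 0 or b <= 0:
                raise InvalidInputError("wall-pair t and b must be > 0")

    @property
    def d_mean(self) -> float:
        return float(np.mean(self.diameters))

    @property
    def d_max(self) -> float:
        return float(np.max(self.diameters))

    @property
    def d_h(self) -> float:
        return hydraulic_diameter(self.diameters)

    def wall_reinforcement(self, near_dh: float | None = None) -> float:
        return wall_reinforcement(self.wall_pairs, d_h=self.d_h, near_dh=near_dh)


@dataclass(frozen=True)
class PitGeometry:
    """Per-pit membrane thickness and chamber depth (nm), averaged over the
    repeated measurements taken on each pit."""

    t_m_readings: tuple[float, ...]
    l_p_readings: tuple[float, ...]
    t_m: float = field(init=False)
    l_p: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.t_m_readings or not self.l_p_readings:
            raise InsufficientDataError("pit needs at least one reading per dimension")
        if any(v <= 0 for v in self.t_m_readings + self.l_p_readings):
            raise InvalidInputError("pit dimensions must be > 0 nm")
        object.__setattr__(self, "t_m", float(np.mean(self.t_m_readings)))
        object.__setattr__(self, "l_p", float(np.mean(self.l_p_readings)))


def diameter_from_area(area: float) -> float:
    """Circular-equivalent diameter (um) of a lumen area (um^2): 2*sqrt(A/pi)."""
    if not (area > 0):
        raise InvalidInputError(f"lumen area must be > 0, got {area!r}")
    return 2.0 * math.sqrt(area / math.pi)


def hydraulic_diameter(diameters: Sequence[float]) -> float:
    """Hydraulically weighted diameter sum(d^5)/sum(d^4) (um).

    Always >= the arithmetic mean, with equality iff all diameters are equal.
    """
    if len(diameters) == 0:
        raise InsufficientDataError("empty diameter list")
    d = np.asarray(diameters, dtype=float)
    if np.any(d <= 0):
        raise InvalidInputError("diameters must be > 0")
    return float(np.sum(d**5) / np.sum(d**4))


def wall_reinforcement(
    pairs: Sequence[tuple[float, float]],
    *,
    d_h: float | None = None,
    near_dh: float | None = None,
) -> float:
    """Mean squared thickness-to-span ratio (t/b)^2 over wall pairs.

    ``near_dh`` optionally restricts pairs to conduits whose diameter b lies
    within +/- that fraction of ``d_h`` (e.g. 0.1 for +/-10%), the convention
    that ties reinforcement to hydraulically relevant conduits. Summaries
    conventionally report the value x 1e3.
    """
    if len(pairs) == 0:
        raise InsufficientDataError("no wall-thickness pairs")
    arr = np.asarray(pairs, dtype=float)
    if np.any(arr <= 0):
        raise InvalidInputError("wall-pair t and b must be > 0")
    if near_dh is not None:
        if d_h is None:
            raise InvalidInputError("near_dh filtering requires d_h")
        mask = np.abs(arr[:, 1] - d_h) <= near_dh * d_h
        if not np.any(mask):
            raise InsufficientDataError(
                f"no wall pairs within +/-{near_dh:.0%} of d_h = {d_h:.2f} um"
            )
        arr = arr[mask]
    return float(np.mean((arr[:, 0] / arr[:, 1]) ** 2))


def diameter_histogram(
    diameters: Sequence[float], bin_width: float = 5.0, *, relative: bool = False
) -> dict[tuple[float, float], float]:
    """Frequency distribution of diameters in [k*w, (k+1)*w) bins.

    Returns a mapping from (bin_lo, bin_hi) to count (or relative frequency
    when ``relative`` is set). Empty input gives an empty histogram.
    """
    if not (bin_width > 0):
        raise InvalidInputError(f"bin width must be > 0, got {bin_width!r}")
    if len(diameters) == 0:
        return {}
    d = np.asarray(diameters, dtype=float)
    idx = np.floor(d / bin_width).astype(int)
    hist: dict[tuple[float, float], float] = {}
    for k in range(int(idx.min()), int(idx.max()) + 1):
        count = int(np.sum(idx == k))
        if count:
            hist[(k * bin_width, (k + 1) * bin_width)] = count
    if relative:
        total = float(len(d))
        hist = {b: c / total for b, c in hist.items()}
    return hist


def hierarchical_mean(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> tuple[float, float | None]:
    """Mean +/- SE across per-sample means (NOT the pooled mean).

    Stage 1 averages within each sample; stage 2 averages the sample means
    and reports their standard error, so samples with many measurements do
    not dominate the group value. SE is None for a single sample.
    """
    seqs = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    if not seqs:
        raise InsufficientDataError("no samples")
    means = []
    for s in seqs:
        if len(s) == 0:
            raise InsufficientDataError("a sample has no measurements")
        means.append(float(np.mean(np.asarray(s, dtype=float))))
    if len(means) == 1:
        logger.warning("hierarchical_mean: single sample, SE undefined")
        return means[0], None
    arr = np.array(means)
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(len(arr)))


def ring_width(
    positions_per_sample: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> tuple[float, float | None]:
    """Ring width per sample = mean of measured positions (five by convention),
    then hierarchical mean across samples."""
    seqs = (
        list(positions_per_sample.values())
        if isinstance(positions_per_sample, Mapping)
        else list(positions_per_sample)
    )
    for s in seqs:
        if len(s) == 1:
            logger.warning("ring_width: a sample has a single position measurement")
    return hierarchical_mean(seqs)
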