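"""Conductance-based quantities: PLC series, specific conductivity, native
embolism and root-system conductance aggregation.

Unit convention: conductance inputs are kg s^-1 MPa^-1 unless stated
otherwise. Specific conductivity assumes water density 1 g cm^-3, so
1 kg s^-1 MPa^-1 corresponds to 1e3 cm^3 s^-1 MPa^-1 of volumetric flow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hydrotraits.errors import InsufficientDataError, InvalidInputError
from hydrotraits.sigmoid_curves import ResponsePoint

logger = logging.getLogger(__name__)

#: kg s^-1 -> cm^3 s^-1 at water density 1 g cm^-3.
KG_TO_CM3 = 1e3


@dataclass(frozen=True)
class ConductanceMeasurement:
    """A single hydraulic conductance reading, optionally at a rotor pressure."""

    k: float
    pressure: float | None = None

    def __post_init__(self) -> None:
        if not (self.k >= 0):
            raise InvalidInputError(f"conductance must be >= 0, got {self.k!r}")


@dataclass(frozen=True)
class SegmentGeometry:
    """Length (cm) and xylem cross-section area (cm^2) of a measured segment."""

    length: float
    xylem_area: float

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise InvalidInputError(f"segment length must be > 0 cm, got {self.length!r}")
        if not (self.xylem_area > 0):
            raise InvalidInputError(
                f"xylem area must be > 0 cm^2, got {self.xylem_area!r}"
            )


def cavitron_plc_series(
    pressures: Sequence[float], conductances: Sequence[float]
) -> list[ResponsePoint]:
    """Percentage loss of conductivity relative to the first measurement.

    The first measurement (least negative pressure) defines the 100%
    reference, so the first point always has PLC = 0. Conductances exceeding
    the reference give negative PLC; these are retained but logged.
    """
    if len(pressures) != len(conductances):
        raise InvalidInputError(
            f"pressure and conductance series differ in length "
            f"({len(pressures)} vs {len(conductances)})"
        )
    if len(pressures) == 0:
        raise InsufficientDataError("empty conductance series")
    k = np.asarray(conductances, dtype=float)
    if np.any(k < 0):
        raise InvalidInputError("conductance values must be >= 0")
    k_ref = float(k[0])
    if k_ref == 0:
        raise InvalidInputError(
            "first (reference) conductance is zero: PLC undefined"
        )
    p = np.asarray(pressures, dtype=float)
    if np.any(np.diff(p) > 0):
        raise InvalidInputError(
            "pressure series must be ordered from least to most negative"
        )
    plc = 100.0 * (1.0 - k / k_ref)
    if np.any(plc < 0):
        logger.warning(
            "cavitron_plc_series: %d conductance(s) exceed the reference; "
            "negative PLC retained",
            int(np.sum(plc < 0)),
        )
    return [ResponsePoint(pressure=float(pi), percent=float(ci)) for pi, ci in zip(p, plc)]


def specific_conductivity(
    k: float, geom: SegmentGeometry, *, k_unit: str = "kg s-1 MPa-1"
) -> float:
    """Specific hydraulic conductivity k_s (cm^2 s^-1 MPa^-1) = k * length / area.

    ``k_unit`` declares the conductance unit: ``"kg s-1 MPa-1"`` (default;
    converted to volumetric flow at water density 1 g cm^-3) or
    ``"cm3 s-1 MPa-1"`` (used as-is).
    """
    if k < 0:
        raise InvalidInputError(f"conductance must be >= 0, got {k!r}")
    if k_unit == "kg s-1 MPa-1":
        k_vol = k * KG_TO_CM3
    elif k_unit == "cm3 s-1 MPa-1":
        k_vol = k
    else:
        raise InvalidInputError(f"unknown conductance unit {k_unit!r}")
    return k_vol * geom.length / geom.xylem_area


def native_plc(k_initial: float, k_flushed: float) -> float:
    """Native/artefactual embolism: 100 * (1 - k_initial / k_flushed).

    A flushed conductance below the initial one is physically impossible
    (flushing removes emboli); the result is floored at 0 with a warning.
    """
    if k_flushed <= 0:
        raise InvalidInputError(f"flushed conductance must be > 0, got {k_flushed!r}")
    if k_initial < 0:
        raise InvalidInputError(f"initial conductance must be >= 0, got {k_initial!r}")
    plc = 100.0 * (1.0 - k_initial / k_flushed)
    if plc < 0:
        logger.warning(
            "native_plc: initial conductance %.4g exceeds flushed %.4g; clamping to 0%%",
            k_initial,
            k_flushed,
        )
        return 0.0
    return plc


def root_conductance(transients: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of repeated root-conductance transients.

    Protocols use 3-5 transients; fewer than 3 triggers a warning but the
    aggregate is still computed (SE is 0 for a single value).
    """
    if len(transients) == 0:
        raise InsufficientDataError("no transient measurements")
    vals = np.asarray(transients, dtype=float)
    if np.any(vals < 0):
        raise InvalidInputError("conductance values must be >= 0")
    if len(vals) < 3:
        logger.warning(
            "root_conductance: only %d transient(s); 3-5 recommended", len(vals)
        )
    if len(vals) > 5:
        logger.warning(
            "root_conductance: %d transients exceed the usual 3-5", len(vals)
        )
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return mean, se
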