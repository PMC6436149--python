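"""Seeded generators emulating the raw measurement series the analyses consume.

All generators are pure functions of their arguments (same seed, same
output) and their outputs pass the corresponding readers' validation
unchanged. Noise models: additive Gaussian in percent space for
vulnerability curves (instrument flow noise is roughly absolute),
Gaussian in 1/psi space for pressure-volume series (pressure-chamber
read-off), multiplicative log-normal for conductances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from hydrotraits.errors import InvalidInputError
from hydrotraits.pressure_volume import PVPoint
from hydrotraits.sigmoid_curves import ResponsePoint, SigmoidFit, percent_at
from hydrotraits.stomata_traits import GasExchangePoint

#: Default rotor pressure schedule: -0.25 to -7.75 MPa in 0.5 MPa steps.
DEFAULT_PRESSURES: tuple[float, ...] = tuple(np.arange(-0.25, -8.0, -0.5))

#: Default WSD sampling schedule for a pressure-volume dehydration series.
DEFAULT_WSD_SCHEDULE: tuple[float, ...] = tuple(np.linspace(0.03, 0.60, 30))


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed plus per-generator design/noise parameters for a full campaign."""

    seed: int
    n_shoots: int = 5
    n_leaves: int = 10
    n_trees: int = 5
    vc_noise_sd: float = 3.0
    pv_noise_sd_invpsi: float = 0.005
    k_noise_cv: float = 0.05
    conduit_n: int = 150
    diurnal_noise: float = 0.05
    extras: dict = field(default_factory=dict)


def gen_vulnerability(
    a: float,
    p50: float,
    pressures: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    raw_k: bool = False,
    k0: float = 1.0,
    k_noise_cv: float = 0.0,
) -> list[ResponsePoint] | tuple[np.ndarray, np.ndarray]:
    """Vulnerability-curve observations from a known sigmoid truth.

    Default mode returns (pressure, percent) points with additive Gaussian
    percent noise of standard deviation ``noise_sd``. With ``raw_k=True``
    the function instead returns (pressures, conductances) with
    k_i = k0 * (1 - PLC_i/100), optionally perturbed by multiplicative
    log-normal noise of coefficient of variation ``k_noise_cv`` — the raw
    series a centrifuge run would produce, for testing the flow pipeline.
    """
    if not (a > 0):
        raise InvalidInputError(f"slope a must be > 0, got {a!r}")
    if not (p50 < 0):
        raise InvalidInputError(f"p50 must be < 0, got {p50!r}")
    if noise_sd < 0 or k_noise_cv < 0:
        raise InvalidInputError("noise parameters must be >= 0")
    p = np.asarray(DEFAULT_PRESSURES if pressures is None else pressures, dtype=float)
    if np.any(p > 0):
        raise InvalidInputError("pressure schedule must be non-positive (MPa)")
    fit = SigmoidFit(a=a, p50=p50)
    plc = np.array([percent_at(fit, pi) for pi in p])
    rng = np.random.default_rng(seed)
    if raw_k:
        if not (k0 > 0):
            raise InvalidInputError(f"k0 must be > 0, got {k0!r}")
        k = k0 * (1.0 - plc / 100.0)
        if k_noise_cv > 0:
            sigma = np.sqrt(np.log(1.0 + k_noise_cv**2))
            k = k * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(k))
        return p, k
    if noise_sd > 0:
        plc = plc + rng.normal(0.0, noise_sd, size=len(plc))
    return [ResponsePoint(pressure=float(pi), percent=float(ci)) for pi, ci in zip(p, plc)]


def pv_psi(psi_osat: float, w_tlp: float, wsd: float) -> float:
    """Mechanistic pressure-volume model: total water potential at a WSD.

    Below the turgor loss point the potential is the sum of an osmotic term
    psi_osat/(1 - W) (solute conservation in the shrinking symplast) and a
    turgor term -psi_osat * (1 - W/w_tlp) that declines linearly to zero at
    w_tlp; beyond w_tlp only the osmotic term remains, which makes 1/psi
    linear in W. The model is continuous at w_tlp with
    psi_tlp = psi_osat / (1 - w_tlp), and psi -> 0- as W -> 0.
    """
    osmotic = psi_osat / (1.0 - wsd)
    if wsd >= w_tlp:
        return osmotic
    return osmotic - psi_osat * (1.0 - wsd / w_tlp)


def gen_pv_leaf(
    psi_osat: float,
    w_tlp: float,
    wsd_schedule: Sequence[float] | None = None,
    noise_sd_invpsi: float = 0.0,
    seed: int | None = None,
) -> list[PVPoint]:
    """Pressure-volume series for one leaf from a known (psi_osat, w_tlp) truth.

    Gaussian noise of standard deviation ``noise_sd_invpsi`` (MPa^-1) is
    added in 1/psi space; noisy 1/psi is clipped just below zero so the
    series always validates as psi < 0.
    """
    if not (psi_osat < 0):
        raise InvalidInputError(f"psi_osat must be < 0, got {psi_osat!r}")
    if not (0.0 < w_tlp < 1.0):
        raise InvalidInputError(f"w_tlp must lie in (0, 1), got {w_tlp!r}")
    if noise_sd_invpsi < 0:
        raise InvalidInputError("noise_sd_invpsi must be >= 0")
    w = np.asarray(
        DEFAULT_WSD_SCHEDULE if wsd_schedule is None else wsd_schedule, dtype=float
    )
    if np.any(w <= 0) or np.any(w > 0.9):
        raise InvalidInputError("WSD schedule values must lie in (0, 0.9]")
    inv_psi = np.array([1.0 / pv_psi(psi_osat, w_tlp, wi) for wi in w])
    if noise_sd_invpsi > 0:
        rng = np.random.default_rng(seed)
        inv_psi = inv_psi + rng.normal(0.0, noise_sd_invpsi, size=len(inv_psi))
        inv_psi = np.minimum(inv_psi, -1e-6)
    return [PVPoint(wsd=float(wi), psi=float(1.0 / ii)) for wi, ii in zip(w, inv_psi)]


def gen_conduits(
    median_um: float, sigma_log: float, n: int, seed: int | None = None
) -> np.ndarray:
    """Right-skewed (log-normal) conduit diameter sample with the given median.

    ``sigma_log = 0`` gives a degenerate sample with every diameter equal to
    the median (so d_h == d_mean).
    """
    if not (median_um > 0):
        raise InvalidInputError(f"median diameter must be > 0, got {median_um!r}")
    if sigma_log < 0:
        raise InvalidInputError(f"sigma_log must be >= 0, got {sigma_log!r}")
    if n <= 0:
        raise InvalidInputError(f"n must be > 0, got {n!r}")
    rng = np.random.default_rng(seed)
    return median_um * np.exp(sigma_log * rng.standard_normal(n))


def gen_diurnal(
    gs_max_true: float,
    psi_min_true: float,
    n_times: int = 53,
    noise: float = 0.0,
    seed: int | None = None,
    *,
    psi_predawn: float = -0.1,
) -> list[GasExchangePoint]:
    """Diurnal gas-exchange course: unimodal g_s with an antiphase psi trough.

    Times run from 05.00 h to 18.00 h. g_s follows a flat-topped bell
    peaking near midday at ``gs_max_true``; psi declines from ``psi_predawn``
    to ``psi_min_true`` in the early afternoon and recovers. With the default
    ``n_times`` the sampling grid contains the psi trough time exactly, so
    the noiseless minimum equals ``psi_min_true``. ``noise`` is a relative
    standard deviation applied to both courses (times gs_max for g_s, times
    |psi_min| for psi).
    """
    if not (gs_max_true > 0):
        raise InvalidInputError(f"gs_max_true must be > 0, got {gs_max_true!r}")
    if not (psi_min_true < psi_predawn < 0):
        raise InvalidInputError(
            f"need psi_min_true < psi_predawn < 0, got {psi_min_true!r}, {psi_predawn!r}"
        )
    if n_times < 2:
        raise InvalidInputError(f"n_times must be >= 2, got {n_times!r}")
    if noise < 0:
        raise InvalidInputError("noise must be >= 0")
    t = np.linspace(5.0, 18.0, n_times)
    gs = gs_max_true * np.exp(-(((t - 12.0) / 4.0) ** 4))
    psi = psi_predawn + (psi_min_true - psi_predawn) * np.exp(-(((t - 13.0) / 4.5) ** 4))
    if noise > 0:
        rng = np.random.default_rng(seed)
        gs = np.maximum(gs + rng.normal(0.0, noise * gs_max_true, size=n_times), 0.0)
        psi = np.minimum(
            psi + rng.normal(0.0, noise * abs(psi_min_true), size=n_times), -1e-3
        )
    return [
        GasExchangePoint(psi_l=float(pi), gs=float(gi), time=f"{ti:05.2f}")
        for ti, gi, pi in zip(t, gs, psi)
    ]
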