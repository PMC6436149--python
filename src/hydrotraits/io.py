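"""CSV readers and writers with schema validation.

Dialect: comma-separated, UTF-8, dot decimal, mandatory header row.
Pressures follow the negative-MPa convention; readers reject positive
pressures unless ``auto_negate`` is set, in which case magnitudes are
negated with a logged notice. Validation errors name the file, row and
column.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from hydrotraits.errors import InvalidInputError
from hydrotraits.pressure_volume import LeafMasses, PVPoint, compute_wsd
from hydrotraits.sigmoid_curves import ResponsePoint
from hydrotraits.stomata_traits import GasExchangePoint

logger = logging.getLogger(__name__)


class SchemaError(InvalidInputError):
    """A CSV file violates its expected schema."""


def _load(path: str | Path, required: Sequence[str], optional: Sequence[str] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file does not exist")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def _check_finite(df: pd.DataFrame, path: str | Path, columns: Sequence[str]) -> None:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(vals)]
        if len(bad):
            raise SchemaError(
                f"{path}: row {int(bad[0]) + 2}, column {col!r}: non-numeric or "
                f"non-finite value {df.loc[bad[0], col]!r}"
            )


def _negative_pressures(
    df: pd.DataFrame, path: str | Path, col: str, auto_negate: bool
) -> pd.Series:
    p = pd.to_numeric(df[col])
    if (p > 0).any():
        if not auto_negate:
            row = int(df.index[p > 0][0]) + 2
            raise SchemaError(
                f"{path}: row {row}, column {col!r}: positive pressure {p[p > 0].iloc[0]}; "
                "pressures are stored as negative MPa. Pass auto_negate=True "
                "(CLI: --auto-negate) to flip magnitudes."
            )
        logger.info("%s: auto-negating %d positive pressure value(s)", path, int((p > 0).sum()))
        p = -p.abs()
    return p


def read_response_csv(
    path: str | Path, auto_negate: bool = False
) -> dict[str, list[ResponsePoint]]:
    """Read (pressure_mpa, percent) series, optionally keyed by ``series_id``."""
    df = _load(path, ["pressure_mpa", "percent"])
    _check_finite(df, path, ["pressure_mpa", "percent"])
    df = df.assign(pressure_mpa=_negative_pressures(df, path, "pressure_mpa", auto_negate))
    if "series_id" not in df.columns:
        df = df.assign(series_id="series")
    out: dict[str, list[ResponsePoint]] = {}
    for sid, grp in df.groupby("series_id", sort=False):
        out[str(sid)] = [
            ResponsePoint(pressure=float(r.pressure_mpa), percent=float(r.percent))
            for r in grp.itertuples()
        ]
    return out


def read_pv_csv(path: str | Path, auto_negate: bool = False) -> dict[str, list[PVPoint]]:
    """Read pressure-volume series per leaf.

    Accepts either precomputed (``wsd``, ``psi_mpa``) rows or raw mass rows
    (``tw_g``, ``fw_g``, ``dw_g``, ``psi_mpa``), optionally keyed by ``leaf_id``.
    """
    df = _load(path, ["psi_mpa"])
    _check_finite(df, path, ["psi_mpa"])
    df = df.assign(psi_mpa=_negative_pressures(df, path, "psi_mpa", auto_negate))
    if "wsd" in df.columns:
        _check_finite(df, path, ["wsd"])
        wsd = pd.to_numeric(df["wsd"])
    elif {"tw_g", "fw_g", "dw_g"} <= set(df.columns):
        _check_finite(df, path, ["tw_g", "fw_g", "dw_g"])
        wsd = pd.Series(
            [
                compute_wsd(LeafMasses(tw=float(r.tw_g), fw=float(r.fw_g), dw=float(r.dw_g)))
                for r in df.itertuples()
            ],
            index=df.index,
        )
    else:
        raise SchemaError(
            f"{path}: need either a 'wsd' column or the mass columns "
            "('tw_g', 'fw_g', 'dw_g') alongside 'psi_mpa'"
        )
    df = df.assign(wsd=wsd)
    if "leaf_id" not in df.columns:
        df = df.assign(leaf_id="leaf")
    out: dict[str, list[PVPoint]] = {}
    for lid, grp in df.groupby("leaf_id", sort=False):
        out[str(lid)] = [
            PVPoint(wsd=float(r.wsd), psi=float(r.psi_mpa)) for r in grp.itertuples()
        ]
    return out


def read_conductance_csv(
    path: str | Path, auto_negate: bool = False
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read centrifuge (pressure_mpa, k) series, optionally keyed by ``shoot_id``."""
    df = _load(path, ["pressure_mpa", "k"])
    _check_finite(df, path, ["pressure_mpa", "k"])
    df = df.assign(pressure_mpa=_negative_pressures(df, path, "pressure_mpa", auto_negate))
    if "shoot_id" not in df.columns:
        df = df.assign(shoot_id="shoot")
    out = {}
    for sid, grp in df.groupby("shoot_id", sort=False):
        out[str(sid)] = (
            grp["pressure_mpa"].to_numpy(dtype=float),
            grp["k"].to_numpy(dtype=float),
        )
    return out


def read_conduit_csv(path: str | Path) -> dict[str, list[float]]:
    """Read per-sample conduit sizes: ``diameter_um`` or ``lumen_area_um2``."""
    df = _load(path, ["sample_id"])
    if "diameter_um" in df.columns:
        col, convert = "diameter_um", False
    elif "lumen_area_um2" in df.columns:
        col, convert = "lumen_area_um2", True
    else:
        raise SchemaError(
            f"{path}: need a 'diameter_um' or 'lumen_area_um2' column"
        )
    _check_finite(df, path, [col])
    from hydrotraits.anatomy import diameter_from_area

    out: dict[str, list[float]] = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        vals = grp[col].astype(float)
        out[str(sid)] = [
            diameter_from_area(v) if convert else float(v) for v in vals
        ]
    return out


def read_wall_pairs_csv(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read per-sample (t_um, b_um) double-wall/diameter pairs."""
    df = _load(path, ["sample_id", "t_um", "b_um"])
    _check_finite(df, path, ["t_um", "b_um"])
    out: dict[str, list[tuple[float, float]]] = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        out[str(sid)] = [(float(r.t_um), float(r.b_um)) for r in grp.itertuples()]
    return out


def read_gas_exchange_csv(
    path: str | Path, auto_negate: bool = False
) -> dict[str, list[GasExchangePoint]]:
    """Read diurnal/closure courses: ``tree_id, time, gs_mmol, psi_mpa``."""
    df = _load(path, ["gs_mmol", "psi_mpa"])
    _check_finite(df, path, ["gs_mmol", "psi_mpa"])
    df = df.assign(psi_mpa=_negative_pressures(df, path, "psi_mpa", auto_negate))
    if "tree_id" not in df.columns:
        df = df.assign(tree_id="tree")
    out: dict[str, list[GasExchangePoint]] = {}
    for tid, grp in df.groupby("tree_id", sort=False):
        out[str(tid)] = [
            GasExchangePoint(
                psi_l=float(r.psi_mpa),
                gs=float(r.gs_mmol),
                time=str(r.time) if "time" in df.columns else None,
            )
            for r in grp.itertuples()
        ]
    return out


def write_records_csv(path: str | Path, records: Sequence[Mapping[str, Any]]) -> None:
    """Write a list of flat records to CSV with full float precision."""
    if not records:
        raise InvalidInputError("no records to write")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(list(records)).to_csv(path, index=False, float_format="%.17g")


def write_json(path: str | Path, payload: Any) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
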