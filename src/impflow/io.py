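"""File formats: TAC/study CSV, phantom TIFF + JSON sidecar, fit reports.

All text outputs are deterministic (sorted JSON keys, fixed column
order, repr-precision floats) so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile

from .simulate import (BolusParams, CalibFactors, KineticParams,
                       PlanarPhantom, StudyTACs, simulate_study)
from .types import TAC, VALID_UNITS, DataError, TimeGrid

__all__ = [
    "write_tac_csv", "read_tac_csv",
    "write_study_csv", "read_tacs",
    "write_phantom", "read_phantom",
    "write_json", "read_json",
    "params_to_dict", "params_from_dict",
]

logger = logging.getLogger("impflow")

# default unit tags for well-known study/ROI column names
_KNOWN_UNITS = {
    "Cr": "Bq/mL", "Ca": "Bq/mL", "L": "Bq", "l": "Bq", "Cb": "Bq/g",
    "pulmonary_artery": "counts", "brain": "counts", "lungs": "counts",
}
_STUDY_COLUMNS = ["Cr", "Ca", "L", "l", "Cb"]


def write_tac_csv(tac: TAC, path: str | Path) -> None:
    """Single-curve CSV: columns time_min, value, unit (header mandatory)."""
    df = pd.DataFrame({"time_min": tac.times, "value": tac.values,
                       "unit": tac.unit})
    df.to_csv(path, index=False, float_format="%.17g")


def read_tac_csv(path: str | Path) -> TAC:
    df = _read_csv(path, required={"time_min", "value", "unit"})
    unit = str(df["unit"].iloc[0])
    if unit not in VALID_UNITS:
        raise DataError(f"{path}: unknown unit tag {unit!r}")
    return TAC(df["time_min"].to_numpy(float), df["value"].to_numpy(float),
               unit)


def write_study_csv(study: StudyTACs, path: str | Path) -> None:
    """Study CSV: columns time_min, Cr, Ca, L, l, Cb (header mandatory)."""
    cols = {"time_min": study.grid.mid_times}
    for name in _STUDY_COLUMNS:
        cols[name] = getattr(study, name).values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise DataError(f"{path}: malformed CSV ({err})") from err
    cols = set(df.columns)
    missing = required - cols
    # a header-less file yields numeric/unnamed columns
    if missing:
        raise DataError(
            f"{path}: missing required columns {sorted(missing)} "
            "(is the header row present?)"
        )
    t = df["time_min"].to_numpy(float)
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: time_min must be finite and strictly "
                        "increasing")
    return df


def read_tacs(path: str | Path) -> dict[str, TAC]:
    """Read a set of TACs from CSV.

    Accepts either the single-curve dialect (time_min, value, unit) or a
    wide table (time_min plus one column per curve).  Well-known column
    names get their physical unit tag; anything else is tagged
    dimensionless.  Extra non-numeric columns are ignored with a warning.
    """
    df = _read_csv(path, required={"time_min"})
    if {"value", "unit"} <= set(df.columns):
        return {"value": read_tac_csv(path)}
    times = df["time_min"].to_numpy(float)
    out: dict[str, TAC] = {}
    for col in df.columns:
        if col == "time_min":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            logger.warning("%s: ignoring non-numeric column %r", path, col)
            continue
        out[col] = TAC(times, vals.to_numpy(float),
                       _KNOWN_UNITS.get(col, "dimensionless"))
    if not out:
        raise DataError(f"{path}: no curve columns found")
    return out


# ---------------------------------------------------------------------------
# JSON

def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(data: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_jsonify(data), indent=2, sort_keys=True) + "\n"
    )


def read_json(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise DataError(f"{path}: malformed JSON ({err})") from err


def params_to_dict(params: KineticParams) -> dict:
    return _jsonify(params)


def params_from_dict(d: Mapping[str, Any]) -> KineticParams:
    d = dict(d)
    if "bolus" in d and isinstance(d["bolus"], Mapping):
        d["bolus"] = BolusParams(**d["bolus"])
    if "calib" in d and isinstance(d["calib"], Mapping):
        d["calib"] = CalibFactors(**d["calib"])
    return KineticParams(**d)


# ---------------------------------------------------------------------------
# phantom TIFF + sidecar

def write_phantom(phantom: PlanarPhantom, stem: str | Path) -> Path:
    """Write a phantom as ``<stem>.tif`` (multi-page frames), one
    single-page mask TIFF per ROI, and a ``<stem>.json`` sidecar carrying
    the grid, pixel size, noise/seed and truth kinetic parameters."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    frames = phantom.frames
    if phantom.noise == "poisson":
        frames = frames.astype(np.uint32)
    tifffile.imwrite(stem.with_suffix(".tif"), frames)
    for name, mask in sorted(phantom.roi_masks.items()):
        tifffile.imwrite(stem.parent / f"{stem.name}_mask_{name}.tif",
                         mask.astype(np.uint8))
    truth = phantom.truth
    sidecar = {
        "format": "impflow-phantom-v1",
        "pixel_size_mm": phantom.pixel_size,
        "grid": {
            "frame_start": phantom.grid.frame_start,
            "frame_duration": phantom.grid.frame_duration,
        },
        "noise": phantom.noise,
        "seed": phantom.seed,
        "roi_names": sorted(phantom.roi_masks),
        "truth_params": params_to_dict(truth.params) if truth.params else None,
        "model": "one_tissue",  # re-simulation honours E and k2 as stored
        "kappa": truth.kappa,
        "t1": truth.t1,
    }
    write_json(sidecar, stem.with_suffix(".json"))
    return stem.with_suffix(".tif")


def read_phantom(stem: str | Path) -> PlanarPhantom:
    """Read a phantom written by :func:`write_phantom`.

    The truth curves are reconstructed from the sidecar's kinetic
    parameters (the forward model is deterministic and closed-form).
    """
    stem = Path(stem)
    if stem.suffix in (".tif", ".json"):
        stem = stem.with_suffix("")
    sidecar = read_json(stem.with_suffix(".json"))
    if sidecar.get("format") != "impflow-phantom-v1":
        raise DataError(f"{stem}.json: not an impflow phantom sidecar")
    grid = TimeGrid(np.asarray(sidecar["grid"]["frame_start"], float),
                    np.asarray(sidecar["grid"]["frame_duration"], float))
    frames = np.asarray(tifffile.imread(stem.with_suffix(".tif")))
    if frames.ndim == 2:
        frames = frames[None]
    masks = {}
    for name in sidecar["roi_names"]:
        masks[name] = np.asarray(
            tifffile.imread(stem.parent / f"{stem.name}_mask_{name}.tif")
        ).astype(bool)
    if sidecar.get("truth_params") is None:
        raise DataError(f"{stem}.json: sidecar lacks truth parameters")
    params = params_from_dict(sidecar["truth_params"])
    truth = simulate_study(params, grid, model=sidecar.get("model",
                                                           "one_tissue"))
    return PlanarPhantom(frames=frames.astype(float)
                         if sidecar["noise"] == "none" else frames,
                         pixel_size=float(sidecar["pixel_size_mm"]),
                         roi_masks=masks, grid=grid, truth=truth,
                         noise=sidecar["noise"], seed=sidecar.get("seed"))
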