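"""Reading and writing of image series, label maps, tables and reports.

Image data go to NIfTI (one 4D volume per lesion, shape (rows, cols, 1,
n_TI), float32) with a JSON sidecar holding the inversion times, seed
and provenance hash; label maps are int16 NIfTI; tables are UTF-8 CSV
with a header row; reports are JSON.  A write-read round trip is
lossless at float32 precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .phantom import ImageSeries
from .t1fit import T1Map

__all__ = [
    "write_series",
    "read_series",
    "write_label_map",
    "read_label_map",
    "write_t1_map",
    "read_table",
    "write_table",
    "write_json",
]

log = logging.getLogger("irllc")

_EYE = np.eye(4)


def write_series(series: ImageSeries, out_dir, stem: str) -> list[Path]:
    """Write one lesion's IR series (+ optional comparator) and sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    vol = np.transpose(series.data.astype(np.float32), (1, 2, 0))[:, :, None, :]
    ir_path = out_dir / f"{stem}_ir.nii.gz"
    nib.save(nib.Nifti1Image(vol, _EYE), ir_path)
    written.append(ir_path)
    if series.vibe is not None:
        vibe_path = out_dir / f"{stem}_vibe.nii.gz"
        nib.save(nib.Nifti1Image(series.vibe.astype(np.float32)[:, :, None], _EYE), vibe_path)
        written.append(vibe_path)
    sidecar = {
        "ti_list_ms": list(series.ti_list_ms),
        "seed": series.seed,
        "meta": series.meta,
        "config_hash": series.config_hash(),
        "has_vibe": series.vibe is not None,
    }
    sc_path = out_dir / f"{stem}_series.json"
    sc_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    written.append(sc_path)
    return written


def read_series(out_dir, stem: str) -> ImageSeries:
    """Read a series written by :func:`write_series`.

    Raises :class:`FormatError` when the sidecar TI count does not match
    the number of stored volumes.
    """
    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / f"{stem}_series.json").read_text())
    vol = np.asanyarray(nib.load(out_dir / f"{stem}_ir.nii.gz").dataobj)
    data = np.transpose(vol[:, :, 0, :], (2, 0, 1)).astype(np.float32)
    ti = sidecar["ti_list_ms"]
    if len(ti) != data.shape[0]:
        raise FormatError(
            f"{stem}: sidecar lists {len(ti)} TIs but volume holds {data.shape[0]}"
        )
    vibe = None
    if sidecar.get("has_vibe"):
        vibe = np.asanyarray(nib.load(out_dir / f"{stem}_vibe.nii.gz").dataobj)[:, :, 0]
    return ImageSeries(
        data=data,
        ti_list_ms=tuple(float(t) for t in ti),
        vibe=vibe,
        seed=sidecar.get("seed"),
        meta=sidecar.get("meta", {}),
    )


def write_label_map(label_map: np.ndarray, out_dir, stem: str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}_label.nii.gz"
    nib.save(nib.Nifti1Image(label_map.astype(np.int16)[:, :, None], _EYE), path)
    return path


def read_label_map(out_dir, stem: str) -> np.ndarray:
    return np.asanyarray(
        nib.load(Path(out_dir) / f"{stem}_label.nii.gz").dataobj
    )[:, :, 0].astype(np.int16)


def write_t1_map(t1_map: T1Map, out_dir, stem: str) -> list[Path]:
    """T1 map as float NIfTI (ms) plus a JSON diagnostics summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}_t1map.nii.gz"
    nib.save(nib.Nifti1Image(t1_map.t1_ms.astype(np.float32)[:, :, None], _EYE), path)
    diag = {
        "n_fitted": int(t1_map.mask.sum()),
        "n_converged": int(t1_map.converged.sum()),
        "median_rss": float(np.nanmedian(t1_map.rss)),
    }
    dpath = out_dir / f"{stem}_t1map.json"
    dpath.write_text(json.dumps(diag, indent=2))
    return [path, dpath]


_KNOWN_TABLE_COLUMNS = {
    "patient_id", "lesion_id", "entity", "condition", "si_liver", "si_lesion",
    "llc", "roi_radius_px", "missing_reason", "diameter_mm", "t1_lesion_ms",
    "t1_liver_ms", "m0_ratio", "has_necrosis", "compartment", "t1_ms",
    "t1_star_ms", "rss", "converged", "n_pixels", "seed",
}


def write_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    """Read a CSV table; unknown columns are preserved with a warning."""
    table = pd.read_csv(path)
    unknown = [c for c in table.columns if c not in _KNOWN_TABLE_COLUMNS]
    if unknown:
        log.warning("unknown column(s) preserved in %s: %s", path, unknown)
    return table


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))
    return path
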