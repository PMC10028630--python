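"""File I/O: NIfTI volumes via nibabel, tables as TSV/CSV, reports as JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import DynamicROI, GazeRecord

__all__ = [
    "save_volume",
    "load_volume",
    "save_bold",
    "load_bold",
    "write_tsv",
    "read_tsv",
    "write_json",
    "read_json",
    "save_gaze_csv",
    "load_gaze_csv",
    "save_roi_tracks",
    "load_roi_tracks",
    "file_sha256",
]


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray | None = None,
                sidecar: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    if sidecar is not None:
        write_json(path.with_suffix("").with_suffix(".json"), sidecar)
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_bold(path: str | Path, data: np.ndarray, tr_seconds: float,
              affine: np.ndarray | None = None, sidecar: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          np.eye(4) if affine is None else affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], tr_seconds))
    nib.save(img, str(path))
    meta = {"tr_seconds": tr_seconds}
    if sidecar:
        meta.update(sidecar)
    write_json(path.with_suffix("").with_suffix(".json"), meta)
    return path


def load_bold(path: str | Path) -> tuple[np.ndarray, float, np.ndarray, dict]:
    img = nib.load(str(path))
    meta_path = Path(path).with_suffix("").with_suffix(".json")
    meta = read_json(meta_path) if meta_path.exists() else {}
    tr = float(meta.get("tr_seconds", img.header.get_zooms()[3]))
    return np.asarray(img.get_fdata()), tr, img.affine, meta


def write_tsv(path: str | Path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_gaze_csv(path: str | Path, gaze: GazeRecord) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "t_ms": gaze.t_ms,
            "x_deg": gaze.x_deg,
            "y_deg": gaze.y_deg,
            "valid": gaze.valid.astype(int),
        }
    ).to_csv(path, index=False)
    return path


def load_gaze_csv(path: str | Path, sample_rate: float | None = None,
                  subject_id: str = "", clip_id: str = "") -> GazeRecord:
    df = pd.read_csv(path)
    t = df["t_ms"].to_numpy(float)
    if sample_rate is None:
        sample_rate = 1000.0 / float(np.median(np.diff(t)))
    valid = df["valid"].to_numpy() if "valid" in df else np.ones(len(df))
    return GazeRecord(
        t_ms=t,
        x_deg=df["x_deg"].to_numpy(float),
        y_deg=df["y_deg"].to_numpy(float),
        valid=valid.astype(bool),
        sample_rate=sample_rate,
        subject_id=subject_id,
        clip_id=clip_id,
    )


def save_roi_tracks(path: str | Path, rois: list[DynamicROI]) -> Path:
    payload = [
        {
            "name": r.name,
            "actor_sex": r.actor_sex,
            "frame_rate": r.frame_rate,
            "polygons": [p.tolist() for p in r.polygons],
        }
        for r in rois
    ]
    return write_json(path, {"rois": payload})


def load_roi_tracks(path: str | Path) -> list[DynamicROI]:
    data = read_json(path)
    return [
        DynamicROI(
            name=r["name"],
            actor_sex=r["actor_sex"],
            polygons=tuple(np.asarray(p) for p in r["polygons"]),
            frame_rate=r["frame_rate"],
        )
        for r in data["rois"]
    ]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
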