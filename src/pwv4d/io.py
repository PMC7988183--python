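"""File formats: NIfTI volumes, CSV tables, JSON reports.

Volumes are written as NIfTI with the voxel spacing in the affine and the
frame duration in a small JSON sidecar (``<file>.meta.json``); velocity
can be stored as one 5-D file (x, y, z, frame, component) or as three 4-D
component files. Tables are tidy CSV with units embedded in the column
names (s_mm, t_ms, Q_mLps, v_cmps) to prevent silent unit drift.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Centerline, FlowWaveform, ImageVolume, LumenMask, VelocityField4D

__all__ = [
    "save_velocity_field",
    "load_velocity_field",
    "save_image_volume",
    "load_image_volume",
    "save_mask",
    "load_mask",
    "waveforms_to_frame",
    "frame_to_waveforms",
    "centerline_to_frame",
    "frame_to_centerline",
    "dump_json",
]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".meta.json")


def _write_meta(path: Path, meta: dict) -> None:
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True, indent=1))


def _read_meta(path: Path) -> dict:
    sc = _sidecar(path)
    return json.loads(sc.read_text()) if sc.exists() else {}


def save_velocity_field(
    field: VelocityField4D, path: str | Path, split_components: bool = False
) -> list[Path]:
    """Write a velocity field as one 5-D NIfTI or three 4-D component files."""
    path = Path(path)
    aff = _affine(field.spacing, field.origin)
    meta = {"frame_ms": field.frame_ms, "venc_cmps": field.venc, "units": "cm/s"}
    written = []
    if split_components:
        for c, tag in enumerate("xyz"):
            p = path.with_name(path.name.replace(".nii", f"_{tag}.nii"))
            nib.save(nib.Nifti1Image(field.data[..., c], aff), p)
            _write_meta(p, meta | {"component": tag})
            written.append(p)
    else:
        nib.save(nib.Nifti1Image(field.data, aff), path)
        _write_meta(path, meta)
        written.append(path)
    return written


def load_velocity_field(path: str | Path) -> VelocityField4D:
    """Read a 5-D velocity NIfTI (or the x-component of a split set)."""
    path = Path(path)
    meta = _read_meta(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 4:  # split components: expect _x, _y, _z siblings
        parts = []
        for tag in "xyz":
            p = Path(str(path).replace("_x.nii", f"_{tag}.nii"))
            parts.append(np.asarray(nib.load(p).dataobj, dtype=np.float32))
        data = np.stack(parts, axis=-1)
    aff = img.affine
    return VelocityField4D(
        data,
        spacing=np.diag(aff)[:3].copy(),
        frame_ms=float(meta.get("frame_ms", 1.0)),
        venc=float(meta.get("venc_cmps", np.inf)),
        origin=aff[:3, 3].copy(),
    )


def save_image_volume(vol: ImageVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.spacing, vol.origin)), path)
    _write_meta(path, {"frame_ms": vol.frame_ms})
    return path


def load_image_volume(path: str | Path) -> ImageVolume:
    path = Path(path)
    img = nib.load(path)
    meta = _read_meta(path)
    fm = meta.get("frame_ms")
    return ImageVolume(
        np.asarray(img.dataobj, dtype=np.float32),
        spacing=np.diag(img.affine)[:3].copy(),
        origin=img.affine[:3, 3].copy(),
        frame_ms=float(fm) if fm is not None else None,
    )


def save_mask(mask_data: np.ndarray, spacing, origin, path: str | Path) -> Path:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(np.asarray(mask_data, dtype=np.uint8), _affine(spacing, origin)),
        path,
    )
    return path


def load_mask(path: str | Path) -> LumenMask:
    img = nib.load(Path(path))
    return LumenMask(
        np.asarray(img.dataobj) > 0,
        spacing=np.diag(img.affine)[:3].copy(),
        origin=img.affine[:3, 3].copy(),
    )


def waveforms_to_frame(waveforms: list[FlowWaveform]) -> pd.DataFrame:
    """Tidy per-plane flow table with columns plane, s_mm, t_ms, Q_mLps."""
    rows = []
    for i, w in enumerate(waveforms):
        pid = w.plane_id if w.plane_id is not None else i
        for t, q in zip(w.time_ms, w.flow_mlps):
            rows.append({"plane": pid, "s_mm": w.s, "t_ms": t, "Q_mLps": q})
    return pd.DataFrame(rows)


def frame_to_waveforms(df: pd.DataFrame, RR: float | None = None) -> list[FlowWaveform]:
    out = []
    for pid, grp in df.groupby("plane", sort=True):
        grp = grp.sort_values("t_ms")
        out.append(
            FlowWaveform(
                grp["t_ms"].to_numpy(),
                grp["Q_mLps"].to_numpy(),
                RR=RR,
                s=float(grp["s_mm"].iloc[0]),
                plane_id=int(pid),
            )
        )
    return out


def centerline_to_frame(cl: Centerline) -> pd.DataFrame:
    inv = {}
    for name, s in cl.landmarks.items():
        inv[int(np.argmin(np.abs(cl.s - s)))] = name
    return pd.DataFrame(
        {
            "x_mm": cl.points[:, 0],
            "y_mm": cl.points[:, 1],
            "z_mm": cl.points[:, 2],
            "s_mm": cl.s,
            "label": [inv.get(i, "") for i in range(len(cl.s))],
        }
    )


def frame_to_centerline(df: pd.DataFrame) -> Centerline:
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy()
    lm = {}
    if "label" in df:
        for _, row in df[df["label"].astype(str).str.len() > 0].iterrows():
            lm[str(row["label"])] = float(row["s_mm"])
    return Centerline(pts, lm)


def dump_json(obj: dict, path: str | Path) -> Path:
    """Deterministic JSON dump (sorted keys, fixed float formatting)."""
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=_default) + "\n")
    return path
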