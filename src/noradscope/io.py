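"""Reading and writing the pipeline's on-disk formats.

Movies are multi-page TIFFs (page order t-major, then z) with a JSON
sidecar of acquisition metadata; histology images and masks are plain
TIFFs; traces, labels and density tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .histo import HistoImage
from .twop import Recording4D, RoiTraceSet

__all__ = [
    "write_recording",
    "read_recording",
    "write_histo_image",
    "read_histo_image",
    "write_traces_csv",
    "write_labels_csv",
    "write_trajectory_csvs",
    "read_trajectory_csvs",
]

_SIDECAR_KEYS = ("frame_rate_hz", "stim_frame", "pixel_size_um")


def write_recording(rec: Recording4D, path: str | Path) -> Path:
    """Write a (t, z, y, x) movie as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    t, z, h, w = rec.data.shape
    tifffile.imwrite(path, rec.data.reshape(t * z, h, w), photometric="minisblack")
    meta = dict(
        frame_rate_hz=rec.frame_rate_hz,
        stim_frame=rec.stim_frame,
        pixel_size_um=rec.pixel_size_um,
        n_frames=t,
        n_z=z,
        animal_id=rec.animal_id,
        fov_id=rec.fov_id,
    )
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> Recording4D:
    """Read a movie written by :func:`write_recording`."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} missing keys {missing}")
    pages = tifffile.imread(path)
    t, z = int(meta["n_frames"]), int(meta["n_z"])
    data = np.asarray(pages).reshape(t, z, *pages.shape[1:])
    return Recording4D(
        data=data,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        stim_frame=int(meta["stim_frame"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        animal_id=str(meta.get("animal_id", "animal0")),
        fov_id=str(meta.get("fov_id", "fov0")),
    )


def write_histo_image(img: HistoImage, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(img.pixels, np.float32), photometric="minisblack"
    )
    meta = dict(
        pixel_size_um=img.pixel_size_um,
        channel=img.channel,
        animal_id=img.animal_id,
        slice_id=img.slice_id,
    )
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_histo_image(path: str | Path) -> HistoImage:
    path = Path(path)
    pixels = tifffile.imread(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return HistoImage(
        pixels=pixels,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        channel=str(meta.get("channel", "NET")),
        animal_id=str(meta.get("animal_id", "animal0")),
        slice_id=str(meta.get("slice_id", "slice0")),
    )


def write_traces_csv(sets: Sequence[RoiTraceSet], path: str | Path) -> Path:
    """Per-ROI trace matrix: rows = ROI (animal, FOV, tile), cols = frames."""
    rows = []
    for s in sets:
        for i in range(s.n_rois):
            row = dict(animal_id=s.animal_id, fov_id=s.fov_id, roi=i)
            row.update({f"f{j + 1}": v for j, v in enumerate(s.traces[i])})
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return Path(path)


def write_labels_csv(sets: Sequence[RoiTraceSet], path: str | Path) -> Path:
    rows = [
        dict(
            animal_id=s.animal_id,
            fov_id=s.fov_id,
            roi=i,
            label=s.labels[i],
            response_stat=s.response_stat[i],
            baseline_sd=s.baseline_sd[i],
            baseline_brightness=s.baseline_brightness[i],
        )
        for s in sets
        for i in range(s.n_rois)
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return Path(path)


def write_trajectory_csvs(
    top: pd.DataFrame, side: pd.DataFrame, top_path: str | Path, side_path: str | Path
) -> tuple[Path, Path]:
    top.to_csv(top_path, index=False)
    side.to_csv(side_path, index=False)
    return Path(top_path), Path(side_path)


def read_trajectory_csvs(
    top_path: str | Path, side_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    return pd.read_csv(top_path), pd.read_csv(side_path)
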