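"""Olfactory-behaviour metrics.

Fuses two synchronised orthogonal camera views (top: x,y; side: x,z) of a
tracked nose point into a 3D trajectory, measures distance to a fixed
odour-source tip, time and entries in the < 2 cm investigation zone, and
group contrasts of buried-food latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Session3D",
    "LatencyContrast",
    "default_phase_schedule",
    "label_phases",
    "fuse_views",
    "distance_to_tip",
    "zone_time",
    "zone_entries",
    "latency_contrast",
]

PHASES = ("baseline", "odour_low", "break", "odour_high")


@dataclass
class Session3D:
    """Fused 3D nose trajectory for one session.

    positions are (n_frames, 3) in cm; ``interpolated`` flags frames that
    were present in only one camera view and filled in linearly; ``phases``
    optionally labels each frame with the stimulus phase.
    """

    positions: np.ndarray
    fps: float
    tip: tuple[float, float, float]
    frames: np.ndarray | None = None
    interpolated: np.ndarray | None = None
    phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_frames, 3)")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        n = self.positions.shape[0]
        if self.frames is None:
            self.frames = np.arange(n)
        if self.interpolated is None:
            self.interpolated = np.zeros(n, bool)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class LatencyContrast:
    mean_control: float
    sem_control: float
    mean_case: float
    sem_case: float
    percent_change: float


def default_phase_schedule() -> list[tuple[str, float]]:
    """Phase schedule of the odour-sensitivity test, (label, seconds).

    Two ascending odour concentrations presented 2 min each with a 1 min
    break in between, preceded by a 2 min no-odour baseline.
    """
    return [
        ("baseline", 120.0),
        ("odour_low", 120.0),
        ("break", 60.0),
        ("odour_high", 120.0),
    ]


def label_phases(
    n_frames: int, fps: float, schedule: Sequence[tuple[str, float]] | None = None
) -> np.ndarray:
    """Per-frame phase labels from a (label, duration_s) schedule."""
    if schedule is None:
        schedule = default_phase_schedule()
    labels = np.array([""] * n_frames, dtype=object)
    start = 0
    for name, dur in schedule:
        stop = min(n_frames, start + int(round(dur * fps)))
        labels[start:stop] = name
        start = stop
    if start < n_frames:
        labels[start:] = schedule[-1][0]
    return labels.astype(str)


def fuse_views(
    top: pd.DataFrame,
    side: pd.DataFrame,
    fps: float,
    tip: tuple[float, float, float],
    scale_top_cm_per_px: float = 1.0,
    scale_side_cm_per_px: float = 1.0,
    phases: np.ndarray | None = None,
) -> Session3D:
    """Fuse top (frame,x,y) and side (frame,x,z) views into 3D positions.

    The x axis is shared between views; the fused x is the mean of the two
    scaled estimates. Frames present in only one view are linearly
    interpolated in the other and flagged. Frame ranges must overlap.
    """
    top = top.sort_values("frame").reset_index(drop=True)
    side = side.sort_values("frame").reset_index(drop=True)
    for df, cols in ((top, ("x", "y")), (side, ("x", "z"))):
        missing = {"frame", *cols} - set(df.columns)
        if missing:
            raise ValueError(f"view table missing columns {sorted(missing)}")
    t0 = max(top["frame"].min(), side["frame"].min())
    t1 = min(top["frame"].max(), side["frame"].max())
    if t0 > t1:
        raise ValueError("camera views cover disjoint frame ranges")

    frames = np.arange(int(t0), int(t1) + 1)

    def _interp(df: pd.DataFrame, col: str, scale: float):
        present = np.isin(frames, df["frame"].to_numpy())
        vals = np.interp(frames, df["frame"], df[col] * scale)
        return vals, present

    x_top, p_top = _interp(top, "x", scale_top_cm_per_px)
    y_top, _ = _interp(top, "y", scale_top_cm_per_px)
    x_side, p_side = _interp(side, "x", scale_side_cm_per_px)
    z_side, _ = _interp(side, "z", scale_side_cm_per_px)

    positions = np.column_stack([(x_top + x_side) / 2.0, y_top, z_side])
    return Session3D(
        positions=positions,
        fps=fps,
        tip=tuple(float(v) for v in tip),
        frames=frames,
        interpolated=~(p_top & p_side),
        phases=phases,
    )


def distance_to_tip(session: Session3D) -> np.ndarray:
    """Per-frame Euclidean nose-to-tip distance in cm."""
    return np.linalg.norm(session.positions - np.asarray(session.tip), axis=1)


def _zone_mask(
    dist: np.ndarray,
    radius_cm: float,
    phases: np.ndarray | None,
    phase: str | None,
) -> np.ndarray:
    mask = np.asarray(dist, float) < radius_cm  # strict: exactly 2 cm is outside
    if phase is not None:
        if phases is None:
            raise ValueError("phase filter requested but no phase labels given")
        mask = mask & (np.asarray(phases) == phase)
    return mask


def zone_time(
    dist: np.ndarray,
    fps: float,
    radius_cm: float = 2.0,
    phases: np.ndarray | None = None,
    phase: str | None = None,
) -> float:
    """Seconds with the nose inside the investigation zone (< radius).

    Frames at exactly the radius are outside. With ``phase`` given, only
    frames of that stimulus phase are counted.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    return float(_zone_mask(dist, radius_cm, phases, phase).sum()) / fps


def zone_entries(
    dist: np.ndarray,
    radius_cm: float = 2.0,
    min_gap_frames: int = 5,
    phases: np.ndarray | None = None,
    phase: str | None = None,
) -> int:
    """Count outside-to-inside zone transitions, with debouncing.

    Exits shorter than ``min_gap_frames`` are ignored (treated as one
    continuous visit), so brief tracking flickers do not inflate the count.
    A session that starts inside the zone counts the initial visit.
    """
    if min_gap_frames < 0:
        raise ValueError("min_gap_frames must be >= 0")
    inside = _zone_mask(dist, radius_cm, phases, phase)
    entries = 0
    last_exit = None  # index after the most recent inside run ended
    prev = False
    for i, cur in enumerate(inside):
        if cur and not prev:
            if entries and last_exit is not None and (i - last_exit) < min_gap_frames:
                pass  # re-entry after a brief excursion: same visit
            else:
                entries += 1
        if prev and not cur:
            last_exit = i
        prev = cur
    return entries


def latency_contrast(
    table: pd.DataFrame, control: str, case: str
) -> LatencyContrast:
    """Group means ± SEM and the percent latency change of case vs control."""
    for col in ("group", "latency_s"):
        if col not in table.columns:
            raise ValueError(f"latency table missing column {col!r}")
    if (table["latency_s"] <= 0).any():
        raise ValueError("latencies must be > 0")
    groups = {}
    for name in (control, case):
        vals = table.loc[table["group"] == name, "latency_s"].to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"group {name!r} not present in table")
        groups[name] = vals
    c, a = groups[control], groups[case]

    def _sem(v: np.ndarray) -> float:
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0

    return LatencyContrast(
        mean_control=float(c.mean()),
        sem_control=_sem(c),
        mean_case=float(a.mean()),
        sem_case=_sem(a),
        percent_change=100.0 * (a.mean() - c.mean()) / c.mean(),
    )
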