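"""Two-photon sensor-movie analysis.

Implements the odour-evoked fluorescence pipeline for GRAB-type
neuromodulator sensor recordings: z-projection, optional rigid motion
correction, baseline-window dF/F normalisation, division of each field of
view (FOV) into a 6x6 grid of 36 subtile ROIs, a response-window statistic,
increase/decrease/none classification against the baseline noise, pooled
response fractions, and the brightest-ROI grand average per animal.

Conventions
-----------
Frames are numbered 1-based in all user-facing windows, matching how
acquisition software and the figures count them; they are converted to
0-based half-open ranges internally. The defaults encode a ~3 min recording
at 1.13 Hz: baseline frames 20-67, air puff at frame 68, response window
frames 89-91, with the first 20 frames flagged invalid (animal startle and
settling at recording onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "Recording4D",
    "AnalysisWindows",
    "TileGrid",
    "DffMovie",
    "RoiTraceSet",
    "project_z",
    "rigid_correct",
    "compute_dff",
    "long_mode_dff",
    "tile_grid",
    "roi_traces",
    "window_response",
    "classify_response",
    "response_fractions",
    "grand_average",
]

LABELS = ("increase", "decrease", "none")


@dataclass
class Recording4D:
    """One FOV's raw movie, shape (t, z, y, x), with acquisition metadata.

    Attributes
    ----------
    data:
        Non-negative raw fluorescence, time-major.
    frame_rate_hz:
        Acquisition rate of full volumes (frames), Hz.
    stim_frame:
        1-based index of the first stimulus (air puff) frame.
    pixel_size_um:
        Lateral pixel size in micrometres.
    animal_id, fov_id:
        Identifiers used for grouping and reporting.
    """

    data: np.ndarray
    frame_rate_hz: float
    stim_frame: int
    pixel_size_um: float
    animal_id: str = "animal0"
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (t, z, y, x) data, got ndim={self.data.ndim}")
        t = self.data.shape[0]
        if not (1 <= self.stim_frame <= t):
            raise ValueError(f"stim_frame {self.stim_frame} outside [1, {t}]")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class AnalysisWindows:
    """1-based inclusive frame windows for the dF/F analysis.

    ``baseline`` is the F0 window B, ``response`` the statistic window W.
    ``drop_first`` frames at recording onset are excluded from downstream
    statistics (but kept in arrays, flagged invalid, so frame numbering
    stays aligned with the acquisition's). Note B starts at frame 20, the
    last dropped frame: F0 uses the full window B, while trace statistics
    such as the baseline sd are restricted to retained frames.
    """

    drop_first: int = 20
    baseline: tuple[int, int] = (20, 67)
    response: tuple[int, int] = (89, 91)
    stim_frame: int = 68

    def __post_init__(self) -> None:
        b0, b1 = self.baseline
        r0, r1 = self.response
        if not (1 <= b0 <= b1):
            raise ValueError(f"invalid baseline window {self.baseline}")
        if not (r0 <= r1):
            raise ValueError(f"invalid response window {self.response}")
        if b1 >= self.stim_frame:
            raise ValueError("baseline window must precede the stimulus frame")
        if r0 < self.stim_frame:
            raise ValueError("response window must follow the stimulus frame")

    # 0-based half-open slices
    @property
    def baseline_slice(self) -> slice:
        return slice(self.baseline[0] - 1, self.baseline[1])

    @property
    def response_slice(self) -> slice:
        return slice(self.response[0] - 1, self.response[1])

    def valid_frames(self, n_frames: int) -> np.ndarray:
        """Boolean retained-frame mask of length ``n_frames``."""
        mask = np.ones(n_frames, dtype=bool)
        mask[: min(self.drop_first, n_frames)] = False
        return mask


@dataclass(frozen=True)
class TileGrid:
    """A rows x cols partition of the FOV into half-open pixel rectangles."""

    rows: int
    cols: int
    height: int
    width: int
    tile_bounds: tuple[tuple[int, int, int, int], ...]  # (y0, y1, x0, x1)

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    def tile_slices(self, index: int) -> tuple[slice, slice]:
        y0, y1, x0, x1 = self.tile_bounds[index]
        return slice(y0, y1), slice(x0, x1)


@dataclass
class DffMovie:
    """dF/F movie with per-frame validity and per-pixel exclusion flags."""

    data: np.ndarray            # (t, y, x), NaN at excluded pixels
    f0: np.ndarray              # (y, x) baseline means
    valid_frames: np.ndarray    # (t,) bool, False for dropped onset frames
    excluded_pixels: np.ndarray  # (y, x) bool, True where F0 <= floor
    windows: AnalysisWindows

    @property
    def n_excluded(self) -> int:
        return int(self.excluded_pixels.sum())


@dataclass
class RoiTraceSet:
    """Per-ROI dF/F traces and summary statistics for one FOV."""

    traces: np.ndarray              # (n_roi, t)
    baseline_brightness: np.ndarray  # (n_roi,) mean raw F over B
    baseline_sd: np.ndarray          # (n_roi,) sd of dF/F trace over B
    response_stat: np.ndarray        # (n_roi,) mean dF/F over W
    labels: list[str]
    grid: TileGrid
    windows: AnalysisWindows
    animal_id: str = "animal0"
    fov_id: str = "fov0"

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]


def project_z(rec: Recording4D | np.ndarray) -> np.ndarray:
    """Collapse the z-dimension by summation: (t, z, y, x) -> (t, y, x).

    The sum projection pools the sensor signal of the full imaged depth into
    one plane per time point, as the downstream tiling analysis expects.
    """
    data = rec.data if isinstance(rec, Recording4D) else np.asarray(rec)
    if data.ndim != 4:
        raise ValueError(f"expected (t, z, y, x), got ndim={data.ndim}")
    if data.size == 0:
        raise ValueError("empty stack")
    return data.sum(axis=1)


def rigid_correct(
    movie: np.ndarray, max_shift: int = 5
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Integer rigid registration of each frame against the temporal mean.

    A whole-frame translation (dy, dx) is estimated per frame by phase
    correlation against the movie's temporal mean, clamped to ``max_shift``
    pixels per axis, and applied with edge padding. This removes bulk
    lateral drift only; non-rigid tissue deformation is out of scope.
    ``max_shift=0`` is the identity.
    """
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("expected a (t, y, x) movie")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if max_shift == 0:
        return movie.copy(), [(0, 0)] * movie.shape[0]

    template = movie.mean(axis=0)
    out = np.empty_like(movie)
    shifts: list[tuple[int, int]] = []
    for i, frame in enumerate(movie):
        shift, _, _ = phase_cross_correlation(
            template, frame, upsample_factor=1, normalization=None
        )
        dy = int(np.clip(round(shift[0]), -max_shift, max_shift))
        dx = int(np.clip(round(shift[1]), -max_shift, max_shift))
        if (dy, dx) == (0, 0):
            out[i] = frame
        else:
            out[i] = ndimage.shift(frame, (dy, dx), order=0, mode="nearest")
        shifts.append((dy, dx))
    return out, shifts


def compute_dff(
    movie: np.ndarray,
    win: AnalysisWindows | None = None,
    normalization: str = "pixel",
    f0_floor_rel: float = 1e-6,
) -> DffMovie:
    """Normalise a (t, y, x) movie to baseline-window dF/F.

    Per pixel, dF/F(t) = (F(t) - F0) / F0 with F0 the mean raw fluorescence
    over the baseline window B. ``normalization="frame_mean"`` uses one
    scalar F0, the baseline mean of whole-frame means, instead of a
    per-pixel F0.

    Pixels whose F0 falls at or below ``f0_floor_rel`` times the movie's
    global mean (vessel-dark pixels) are flagged, set to NaN, and excluded
    from all tile statistics downstream. Frames before ``win.drop_first``
    are retained in the array but flagged invalid.
    """
    if win is None:
        win = AnalysisWindows()
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError("expected a (t, y, x) movie")
    t = movie.shape[0]
    if win.baseline[1] > t:
        raise ValueError(f"baseline window {win.baseline} exceeds {t} frames")
    if normalization not in ("pixel", "frame_mean"):
        raise ValueError("normalization must be 'pixel' or 'frame_mean'")

    f0 = movie[win.baseline_slice].mean(axis=0)
    floor = f0_floor_rel * movie.mean()
    excluded = f0 <= floor

    if normalization == "frame_mean":
        f0_scalar = movie[win.baseline_slice].mean()
        if f0_scalar <= floor:
            raise ValueError("whole-frame baseline mean at or below the F0 floor")
        dff = (movie - f0_scalar) / f0_scalar
    else:
        safe_f0 = np.where(excluded, 1.0, f0)
        dff = (movie - f0) / safe_f0
    dff[:, excluded] = np.nan

    return DffMovie(
        data=dff,
        f0=f0,
        valid_frames=win.valid_frames(t),
        excluded_pixels=excluded,
        windows=win,
    )


def long_mode_dff(
    movie: np.ndarray, baseline: tuple[int, int] = (20, 300), **kwargs
) -> DffMovie:
    """dF/F for long recordings, normalised to an extended baseline window.

    Identical to :func:`compute_dff` with the alternate baseline range
    (default frames 20-300) used for ~18 min recordings with repeated
    stimuli; the response window is not used here and is placed after the
    baseline only to satisfy window ordering.
    """
    end = baseline[1]
    win = AnalysisWindows(
        baseline=baseline, stim_frame=end + 1, response=(end + 2, end + 2)
    )
    return compute_dff(movie, win, **kwargs)


def _axis_edges(n: int, parts: int) -> np.ndarray:
    """Cut ``n`` pixels into ``parts`` near-equal runs; remainder pixels go
    one each to the first tiles along the axis."""
    base, rem = divmod(n, parts)
    sizes = np.full(parts, base, dtype=int)
    sizes[:rem] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def tile_grid(height: int, width: int, rows: int = 6, cols: int = 6) -> TileGrid:
    """Partition a height x width FOV into a rows x cols grid of subtile ROIs.

    The default 6x6 grid yields the 36 subtiles used throughout the
    analysis. Tiles are half-open rectangles, disjoint and covering.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if height < rows or width < cols:
        raise ValueError(f"grid {rows}x{cols} larger than image {height}x{width}")
    ye = _axis_edges(height, rows)
    xe = _axis_edges(width, cols)
    bounds = tuple(
        (int(ye[r]), int(ye[r + 1]), int(xe[c]), int(xe[c + 1]))
        for r in range(rows)
        for c in range(cols)
    )
    return TileGrid(rows=rows, cols=cols, height=height, width=width, tile_bounds=bounds)


def window_response(trace: np.ndarray, win: AnalysisWindows) -> float:
    """Mean dF/F over the response window W (inclusive 1-based range)."""
    trace = np.asarray(trace)
    if win.response[1] > trace.shape[-1]:
        raise ValueError(
            f"response window {win.response} outside trace of {trace.shape[-1]} frames"
        )
    return float(np.mean(trace[..., win.response_slice]))


def classify_response(response_stat: float, baseline_sd: float, k: float = 2.0) -> str:
    """Label a ROI response against its baseline noise.

    ``increase`` if the response statistic exceeds ``k`` baseline standard
    deviations, ``decrease`` if it falls below ``-k`` of them, else ``none``.
    The dead band keeps near-noise ROIs out of both response classes.
    """
    if baseline_sd < 0:
        raise ValueError("baseline_sd must be >= 0")
    thr = k * baseline_sd
    if response_stat > thr:
        return "increase"
    if response_stat < -thr:
        return "decrease"
    return "none"


def roi_traces(
    dff: DffMovie,
    raw_movie: np.ndarray,
    grid: TileGrid,
    win: AnalysisWindows | None = None,
    k: float = 2.0,
    animal_id: str = "animal0",
    fov_id: str = "fov0",
) -> RoiTraceSet:
    """Reduce a dF/F movie to per-subtile (ROI) traces and statistics.

    Each ROI trace is the mean dF/F over the tile's non-excluded pixels per
    frame; baseline brightness is the mean raw F over the baseline window,
    used later to select the brightest ROIs; the baseline sd is taken over
    retained baseline frames and feeds the response classification.
    """
    if win is None:
        win = dff.windows
    raw_movie = np.asarray(raw_movie, dtype=np.float64)
    if dff.data.shape != raw_movie.shape:
        raise ValueError(
            f"dF/F shape {dff.data.shape} != raw shape {raw_movie.shape}"
        )
    if dff.data.shape[1:] != (grid.height, grid.width):
        raise ValueError(
            f"grid {grid.height}x{grid.width} does not match movie "
            f"{dff.data.shape[1]}x{dff.data.shape[2]}"
        )

    t = dff.data.shape[0]
    n = grid.n_tiles
    traces = np.empty((n, t))
    brightness = np.empty(n)
    base_sd = np.empty(n)
    stats = np.empty(n)
    labels: list[str] = []

    ok = ~dff.excluded_pixels
    base_valid = win.valid_frames(t)[win.baseline_slice]  # retained frames within B
    for i in range(n):
        ys, xs = grid.tile_slices(i)
        tile_ok = ok[ys, xs]
        if not tile_ok.any():
            raise ValueError(
                f"tile {i}: all {tile_ok.size} pixels excluded by the F0 floor"
            )
        traces[i] = dff.data[:, ys, xs][:, tile_ok].mean(axis=1)
        brightness[i] = raw_movie[win.baseline_slice, ys, xs][:, tile_ok].mean()
        base = traces[i, win.baseline_slice][base_valid]
        base_sd[i] = base.std(ddof=0)
        stats[i] = window_response(traces[i], win)
        labels.append(classify_response(stats[i], base_sd[i], k=k))

    return RoiTraceSet(
        traces=traces,
        baseline_brightness=brightness,
        baseline_sd=base_sd,
        response_stat=stats,
        labels=labels,
        grid=grid,
        windows=win,
        animal_id=animal_id,
        fov_id=fov_id,
    )


def response_fractions(labels: Sequence[str]) -> tuple[float, float, float]:
    """Percentages of (increase, decrease, none) labels over all ROIs."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    unknown = set(labels) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    n = len(labels)
    return tuple(100.0 * labels.count(lab) / n for lab in LABELS)  # type: ignore


def grand_average(fov_sets: Sequence[RoiTraceSet], n_brightest: int = 3) -> np.ndarray:
    """Animal-level average trace from the brightest ROIs of each FOV.

    Within each FOV the ``n_brightest`` ROIs by baseline raw brightness are
    selected (avoiding vessel-dark tiles; ties broken by ascending ROI index
    in row-major tile order) and their traces averaged; the per-FOV averages
    are then averaged frame-wise across FOVs.
    """
    if not fov_sets:
        raise ValueError("no FOVs given")
    per_fov = []
    for s in fov_sets:
        if s.n_rois < n_brightest:
            raise ValueError(
                f"FOV {s.fov_id} has {s.n_rois} ROIs, needs >= {n_brightest}"
            )
        order = np.argsort(-s.baseline_brightness, kind="stable")[:n_brightest]
        per_fov.append(s.traces[order].mean(axis=0))
    return np.mean(per_fov, axis=0)
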