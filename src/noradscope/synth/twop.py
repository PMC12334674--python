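"""Synthetic two-photon sensor-movie cohorts with known ROI ground truth.

Emulates the acquisition the analysis expects: ~3 min volumetric recordings
at 1.13 Hz, a 10 s odour air puff starting at frame 68, a textured strictly
positive baseline with vessel-dark tiles, and per-subtile evoked dF/F
plateaus of a few percent. Movies are desk-scale (120x120 px, 8 z-slices by
default); the tiling analysis is size-agnostic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from ..presets import SimPreset
from ..twop import Recording4D, tile_grid
from .groundtruth import GroundTruth

__all__ = ["gen_twop_cohort"]

_RESPONSE_END = 91  # recordings must cover the default response window


def _planted_labels(rng: np.random.Generator, n: int, p_inc: float, p_dec: float):
    """Class labels with exact rounded counts, randomly placed.

    Exact counts (rather than iid Bernoulli draws) keep the pooled cohort
    fractions representative of the class probabilities at the small ROI
    counts the presets use.
    """
    n_inc = int(round(p_inc * n))
    n_dec = int(round(p_dec * n))
    labels = np.array(
        ["increase"] * n_inc + ["decrease"] * n_dec + ["none"] * (n - n_inc - n_dec)
    )
    rng.shuffle(labels)
    return labels


def _baseline_field(
    rng: np.random.Generator, height: int, width: int, grid, vessel_tiles: int
) -> np.ndarray:
    """Smooth, strictly positive brightness texture with dark vessel tiles."""
    tex = ndimage.gaussian_filter(rng.standard_normal((height, width)), sigma=8.0)
    tex = (tex - tex.min()) / max(np.ptp(tex), 1e-12)  # -> [0, 1]
    base = 100.0 * (0.4 + 0.6 * tex)
    dark = rng.choice(grid.n_tiles, size=min(vessel_tiles, grid.n_tiles), replace=False)
    for ti in dark:
        ys, xs = grid.tile_slices(int(ti))
        base[ys, xs] *= 0.05  # vessel-dark but strictly positive
    return base


def gen_twop_cohort(preset: SimPreset) -> tuple[list[Recording4D], GroundTruth]:
    """Generate a cohort of raw 4D recordings plus planted ROI ground truth.

    Each ROI (subtile) of each FOV is assigned a response class; responding
    tiles carry a dF/F plateau of the planted amplitude from the stimulus
    frame onward, on top of the textured baseline and per-voxel Gaussian
    noise scaled so the projected pixel dF/F noise sd equals ``noise_sd``.
    """
    p = dict(preset.params)
    n_frames = int(p["n_frames"])
    stim = int(p["stim_frame"])
    p_inc, p_dec = float(p["p_inc"]), float(p["p_dec"])
    if n_frames < _RESPONSE_END:
        raise ValueError(f"n_frames={n_frames} < response-window end {_RESPONSE_END}")
    if p_inc + p_dec > 1:
        raise ValueError("p_inc + p_dec must not exceed 1")

    n_animals, n_fovs = int(p["n_animals"]), int(p["n_fovs"])
    height, width, n_z = int(p["height"]), int(p["width"]), int(p["n_z"])
    grid = tile_grid(height, width, int(p["grid_rows"]), int(p["grid_cols"]))
    amp = {"increase": float(p["amp_inc"]), "decrease": float(p["amp_dec"]), "none": 0.0}

    root = np.random.SeedSequence(preset.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    n_total = n_animals * n_fovs * grid.n_tiles
    labels = _planted_labels(label_rng, n_total, p_inc, p_dec)

    # step kernel: 0 before the stimulus frame, 1 from it onward (1-based)
    s = (np.arange(1, n_frames + 1) >= stim).astype(np.float32)
    voxel_noise_sd = np.float32(float(p["noise_sd"]) * np.sqrt(n_z))

    recordings: list[Recording4D] = []
    rows = []
    fov_seeds = root.spawn(n_animals * n_fovs + 1)[1:]
    idx = 0
    for a in range(n_animals):
        for f in range(n_fovs):
            rng = np.random.default_rng(fov_seeds[a * n_fovs + f])
            base = _baseline_field(rng, height, width, grid, int(p["vessel_tiles"]))
            fov_labels = labels[idx : idx + grid.n_tiles]
            amp_map = np.zeros((height, width), np.float32)
            for ti, lab in enumerate(fov_labels):
                ys, xs = grid.tile_slices(ti)
                amp_map[ys, xs] = amp[lab]
                rows.append(
                    dict(
                        animal_id=f"animal{a}",
                        fov_id=f"fov{f}",
                        roi=ti,
                        label=lab,
                        amplitude=amp[lab],
                    )
                )
            idx += grid.n_tiles

            rel = 1.0 + amp_map[None, :, :] * s[:, None, None]  # (t, y, x)
            noise = rng.standard_normal(
                (n_frames, n_z, height, width), dtype=np.float32
            )
            data = (base[None, None, :, :] / n_z).astype(np.float32) * (
                rel[:, None, :, :] + voxel_noise_sd * noise
            )
            np.clip(data, 0.0, None, out=data)
            recordings.append(
                Recording4D(
                    data=data,
                    frame_rate_hz=float(p["frame_rate_hz"]),
                    stim_frame=stim,
                    pixel_size_um=float(p["pixel_size_um"]),
                    animal_id=f"animal{a}",
                    fov_id=f"fov{f}",
                )
            )

    truth_df = pd.DataFrame(rows)
    gt = GroundTruth(
        roi_labels=truth_df,
        roi_amplitudes=truth_df["amplitude"].to_numpy(),
        group_params=dict(p_inc=p_inc, p_dec=p_dec, preset=preset.name),
    )
    return recordings, gt
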