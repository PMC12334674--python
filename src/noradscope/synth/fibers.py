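"""Synthetic fibre-stain images with a planted foreground area fraction.

Fibres are rasterised random-walk polylines stamped with a circular brush,
so they meander and overlap like immunostained axons; fibres are added
until the mask reaches the requested area fraction. The image is bright
fibre on dim background plus Gaussian noise, clipped at zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import disk

from .._sampling import stratified_normal
from ..histo import HistoImage
from ..presets import SimPreset
from .groundtruth import GroundTruth

__all__ = ["gen_fiber_image", "gen_fiber_cohort"]

_BACKGROUND = 20.0
_FIBRE = 120.0
_TOL_PP = 1.5  # rasterisation tolerance, percentage points


def _stamp_walk(
    mask: np.ndarray, rng: np.random.Generator, n_steps: int, radius: float
) -> None:
    """Stamp one random-walk fibre of ``n_steps`` unit steps onto the mask."""
    h, w = mask.shape
    y, x = rng.uniform(0, h), rng.uniform(0, w)
    theta = rng.uniform(0, 2 * np.pi)
    for _ in range(n_steps):
        theta += rng.normal(0, 0.35)  # direction persistence
        y = np.clip(y + np.sin(theta), 0, h - 1)
        x = np.clip(x + np.cos(theta), 0, w - 1)
        rr, cc = disk((y, x), max(radius, 0.5), shape=mask.shape)
        mask[rr, cc] = True


def gen_fiber_image(
    area_fraction: float,
    shape: tuple[int, int] = (256, 256),
    fibre_width: int = 3,
    noise_sd: float = 6.0,
    seed: int | np.random.SeedSequence = 0,
    pixel_size_um: float = 0.4,
    channel: str = "NET",
    animal_id: str = "animal0",
    slice_id: str = "slice0",
) -> tuple[HistoImage, np.ndarray]:
    """One fibre image plus its true foreground mask.

    The mask's area fraction lands within ±1.5 percentage points of
    ``area_fraction`` (stamping granularity). ``area_fraction`` must be in
    [0, 60] %: denser targets cannot be laid down as distinguishable fibres.
    """
    if not (0.0 <= area_fraction <= 60.0):
        raise ValueError("area_fraction must be in [0, 60] %")
    if min(shape) < 64:
        raise ValueError("image must be at least 64x64")
    if fibre_width < 1:
        raise ValueError("fibre_width must be >= 1")

    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, bool)
    n_px = mask.size
    target = area_fraction / 100.0 * n_px
    radius = fibre_width / 2.0
    max_fibres = 20000
    for _ in range(max_fibres):
        filled = mask.sum()
        if filled >= target:
            break
        # short fibres near the target so a single stamp cannot overshoot
        remaining = target - filled
        n_steps = int(np.clip(remaining / max(fibre_width, 1), 3, 60))
        _stamp_walk(mask, rng, n_steps, radius)
    else:
        raise ValueError(
            f"area fraction {area_fraction}% unreachable at width {fibre_width} "
            f"on {shape[0]}x{shape[1]}"
        )
    achieved = 100.0 * mask.mean()
    if area_fraction > 0 and abs(achieved - area_fraction) > _TOL_PP:
        raise ValueError(
            f"requested {area_fraction}% but rasterised {achieved:.2f}%"
        )

    img = np.where(mask, _FIBRE, _BACKGROUND).astype(float)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, shape)
    np.clip(img, 0.0, None, out=img)
    histo = HistoImage(
        pixels=img,
        pixel_size_um=pixel_size_um,
        channel=channel,
        animal_id=animal_id,
        slice_id=slice_id,
    )
    return histo, mask


def gen_fiber_cohort(preset: SimPreset) -> tuple[list[HistoImage], GroundTruth]:
    """Two-group fibre-image cohort (control vs case) from a loss preset.

    Per-slice control area fractions follow Normal(control_mean, control_sd),
    drawn by stratified sampling so the small group stays representative;
    case fractions are the same distribution scaled by ``case_scale``, so
    the planted relative loss is (1 - case_scale) x 100 %.
    """
    p = dict(preset.params)
    n_animals, n_slices = int(p["n_animals"]), int(p["n_slices"])
    scale = float(p["case_scale"])
    root = np.random.SeedSequence(preset.seed)
    frac_rng = np.random.default_rng(root.spawn(1)[0])

    n_per_group = n_animals * n_slices
    fractions = {
        "control": stratified_normal(
            frac_rng, n_per_group, float(p["control_mean"]), float(p["control_sd"])
        ),
        "case": scale
        * stratified_normal(
            frac_rng, n_per_group, float(p["control_mean"]), float(p["control_sd"])
        ),
    }

    images: list[HistoImage] = []
    rows = []
    img_seeds = iter(root.spawn(2 * n_per_group + 1)[1:])
    for group, fracs in fractions.items():
        i = 0
        for a in range(n_animals):
            for s in range(n_slices):
                img, mask = gen_fiber_image(
                    float(np.clip(fracs[i], 0.0, 60.0)),
                    shape=tuple(p["shape"]),
                    fibre_width=int(p["fibre_width"]),
                    noise_sd=float(p["noise_sd"]),
                    seed=next(img_seeds),
                    pixel_size_um=float(p["pixel_size_um"]),
                    animal_id=f"{group}_animal{a}",
                    slice_id=f"slice{s}",
                )
                images.append(img)
                rows.append(
                    dict(
                        group=group,
                        animal_id=img.animal_id,
                        slice_id=img.slice_id,
                        area_pct=100.0 * mask.mean(),
                    )
                )
                i += 1

    gt = GroundTruth(
        true_area_fraction=pd.DataFrame(rows),
        group_params=dict(
            control_mean=float(p["control_mean"]),
            control_sd=float(p["control_sd"]),
            case_scale=scale,
            planted_loss_pct=100.0 * (1.0 - scale),
            preset=preset.name,
        ),
    )
    return images, gt
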