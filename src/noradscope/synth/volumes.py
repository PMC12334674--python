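"""Synthetic labelled 3D volumes with known intersection ground truth.

Emulates confocal engulfment stacks: tube-like axons (NET), blob-like
microglia (Iba1) with nested lysosomes (CD68), and an auxiliary channel of
patches on axons (e.g., an "eat-me" surface signal). A configurable
fraction of tubes is routed through cell centres so triple overlaps exist.
All ground-truth intersection volumes are voxel recounts of the generated
masks, not the requested parameters.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from ..coloc import VolumeChannels
from ..presets import SimPreset
from .groundtruth import GroundTruth

__all__ = ["gen_coloc_volumes", "DEFAULT_VOLUME_PARAMS"]

DEFAULT_VOLUME_PARAMS: dict = dict(
    shape=(24, 64, 64),
    voxel_size_um=(0.5, 0.25, 0.25),
    n_cells=3,
    cell_radius_um=4.0,
    n_lysosomes_per_cell=2,
    lysosome_radius_um=1.2,
    n_tubes=4,
    tube_radius_um=0.5,
    engulf_fraction=0.5,
    n_aux_patches=6,
    aux_radius_um=0.8,
)


def _radii_vox(radius_um: float, voxel: tuple[float, float, float]) -> np.ndarray:
    return np.maximum(np.asarray(radius_um) / np.asarray(voxel), 0.5)


def _ellipsoid(shape, center, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, float)
    for g, c, r in zip(grids, center, radii_vox):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _tube(shape, rng, radii_vox, waypoint=None) -> np.ndarray:
    """Random-walk tube across the volume, optionally through a waypoint."""
    mask = np.zeros(shape, bool)
    pos = np.array([rng.uniform(0, s) for s in shape])
    if waypoint is not None:
        pos = np.asarray(waypoint, float) + rng.normal(0, 1.0, 3)
    direction = rng.normal(0, 1.0, 3)
    direction /= np.linalg.norm(direction)
    n_steps = int(1.5 * max(shape))
    for _ in range(n_steps):
        direction += rng.normal(0, 0.15, 3)
        direction /= np.linalg.norm(direction)
        pos = np.clip(pos + direction, 0, np.asarray(shape) - 1)
        mask |= _ellipsoid(shape, pos, radii_vox)
    return mask


def gen_coloc_volumes(
    params: dict | None = None, seed: int | np.random.SeedSequence = 0
) -> tuple[VolumeChannels, GroundTruth]:
    """Generate NET/Iba1/CD68/aux masks plus voxel-recounted intersections.

    ``GroundTruth.true_intersections`` maps each marker pair (and the
    ("cd68", "iba1", "net") triple) to its intersection volume in µm³,
    counted directly on the returned masks.
    """
    p = {**DEFAULT_VOLUME_PARAMS, **(params or {})}
    shape = tuple(p["shape"])
    voxel = tuple(p["voxel_size_um"])
    if p["lysosome_radius_um"] > p["cell_radius_um"]:
        raise ValueError(
            "requested lysosome larger than its parent cell: nested "
            "intersection would exceed the smaller parent volume"
        )
    if not (0.0 <= p["engulf_fraction"] <= 1.0):
        raise ValueError("engulf_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    cell_r = _radii_vox(p["cell_radius_um"], voxel)
    lys_r = _radii_vox(p["lysosome_radius_um"], voxel)
    tube_r = _radii_vox(p["tube_radius_um"], voxel)
    aux_r = _radii_vox(p["aux_radius_um"], voxel)

    iba1 = np.zeros(shape, bool)
    cd68 = np.zeros(shape, bool)
    centers = []
    for _ in range(int(p["n_cells"])):
        # keep the cell inside the volume; centre it on axes too thin for that
        c = np.array(
            [
                rng.uniform(r, s - 1 - r) if s - 1 - r > r else (s - 1) / 2.0
                for s, r in zip(shape, cell_r)
            ]
        )
        centers.append(c)
        iba1 |= _ellipsoid(shape, c, cell_r)
        for _ in range(int(p["n_lysosomes_per_cell"])):
            off = rng.normal(0, 1.0, 3) * cell_r * 0.3
            cd68 |= _ellipsoid(shape, c + off, lys_r)
    cd68 &= iba1  # lysosomes live inside cells

    net = np.zeros(shape, bool)
    n_tubes = int(p["n_tubes"])
    n_engulfed = int(round(p["engulf_fraction"] * n_tubes))
    for i in range(n_tubes):
        waypoint = centers[i % len(centers)] if (i < n_engulfed and centers) else None
        net |= _tube(shape, rng, tube_r, waypoint=waypoint)

    aux = np.zeros(shape, bool)
    net_voxels = np.argwhere(net)
    if net_voxels.size:
        picks = rng.choice(len(net_voxels), size=int(p["n_aux_patches"]), replace=True)
        for i in picks:
            aux |= _ellipsoid(shape, net_voxels[i], aux_r)

    channels = VolumeChannels(
        masks={"net": net, "iba1": iba1, "cd68": cd68, "aux": aux},
        voxel_size_um=voxel,
    )
    voxvol = channels.voxel_volume_um3
    inter: dict[tuple[str, ...], float] = {}
    for a, b in combinations(sorted(channels.masks), 2):
        inter[(a, b)] = float(
            (channels.masks[a] & channels.masks[b]).sum()
        ) * voxvol
    inter[("cd68", "iba1", "net")] = float((net & cd68 & iba1).sum()) * voxvol
    gt = GroundTruth(true_intersections=inter, group_params=dict(p))
    return channels, gt
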