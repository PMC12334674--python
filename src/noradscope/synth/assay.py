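"""Synthetic phagocytic-uptake time courses with a planted group fold."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._sampling import stratified_normal
from ..presets import SimPreset
from .groundtruth import GroundTruth

__all__ = ["gen_phago_series", "gen_phago_from_preset"]


def _mean_curve(t: np.ndarray, plateau: float) -> np.ndarray:
    """Saturating (logistic) mean uptake index over hours."""
    return plateau / (1.0 + np.exp(-(t - 6.0) / 2.5))


def gen_phago_series(
    plateau_control: float = 20.0,
    fold: float = 1.33,
    timepoints=tuple(range(0, 25)),
    noise_cv: float = 0.10,
    n_wells: int = 12,
    seed: int | np.random.SeedSequence = 0,
    include_cytod: bool = False,
    mean_cells: float = 1000.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-well uptake table (group, well_id, time_h, intensity, cells).

    The control mean index follows a logistic curve saturating at
    ``plateau_control``; the case curve is the control curve times ``fold``
    at every time point. Noise is a per-well multiplicative factor with CV
    ``noise_cv`` (stratified draws), modelling well-to-well seeding
    differences. A "cytoD" group with near-zero uptake (actin polymerisation
    blocked) is emitted when requested. The 12 h reference point must be
    among the timepoints.
    """
    t = np.asarray(sorted(timepoints), float)
    if 12.0 not in t:
        raise ValueError("timepoints must include the 12 h reference")
    if plateau_control <= 0:
        raise ValueError("plateau must be > 0")
    root = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    groups = {"control": 1.0, "case": fold}
    if include_cytod:
        groups["cytoD"] = 0.0
    streams = root.spawn(len(groups))

    rows = []
    base = _mean_curve(t, plateau_control)
    for (group, scale), ss in zip(groups.items(), streams):
        rng = np.random.default_rng(ss)
        well_factor = stratified_normal(rng, n_wells, 1.0, noise_cv)
        cells = np.round(stratified_normal(rng, n_wells, mean_cells, 0.05 * mean_cells))
        for w in range(n_wells):
            index = base * scale * max(well_factor[w], 0.05)
            for ti, hour in enumerate(t):
                rows.append(
                    dict(
                        group=group,
                        well_id=f"{group}_w{w}",
                        time_h=float(hour),
                        total_intensity=float(index[ti] * cells[w]),
                        cell_count=float(cells[w]),
                    )
                )
    gt = GroundTruth(
        group_params=dict(
            plateau_control=plateau_control, fold=fold, noise_cv=noise_cv
        )
    )
    return pd.DataFrame(rows), gt


def gen_phago_from_preset(preset: SimPreset):
    p = dict(preset.params)
    return gen_phago_series(
        plateau_control=float(p["plateau_control"]),
        fold=float(p["fold"]),
        timepoints=tuple(p["timepoints"]),
        noise_cv=float(p["noise_cv"]),
        n_wells=int(p["n_wells"]),
        seed=preset.seed,
        include_cytod=bool(p.get("include_cytod", False)),
    )
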