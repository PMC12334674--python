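"""Phagocytosis-assay metrics.

The phagocytic index of a live-cell uptake assay is the total integrated
fluorescence of ingested pH-sensitive cargo per image (RCU·µm²/image)
divided by the number of cells in the image; group time courses are
normalised to the control group at a reference time point (12 h by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["phagocytic_index", "add_index", "normalize_to_control", "GroupFold"]


@dataclass(frozen=True)
class GroupFold:
    group: str
    fold: float
    percent_difference: float
    mean_index: float
    n_wells: int


def phagocytic_index(total_intensity, cell_count):
    """Index = total integrated intensity / cell count (RCU·µm² per cell).

    Rows with zero cells yield NaN (flagged missing, not zero: an image
    without cells carries no uptake information).
    """
    intensity = np.asarray(total_intensity, float)
    cells = np.asarray(cell_count, float)
    if np.any(cells < 0) or np.any(intensity < 0):
        raise ValueError("intensities and cell counts must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(cells > 0, intensity / np.where(cells > 0, cells, 1.0), np.nan)
    if idx.ndim == 0:
        return float(idx)
    return idx


def add_index(series: pd.DataFrame) -> pd.DataFrame:
    """Append a ``phagocytic_index`` column to an uptake table.

    Expects columns (group, well_id, time_h, total_intensity, cell_count).
    """
    required = {"group", "well_id", "time_h", "total_intensity", "cell_count"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"uptake table missing columns {sorted(missing)}")
    out = series.copy()
    out["phagocytic_index"] = phagocytic_index(
        out["total_intensity"].to_numpy(), out["cell_count"].to_numpy()
    )
    return out


def normalize_to_control(
    series: pd.DataFrame, control_group: str, at_time_h: float = 12.0
) -> list[GroupFold]:
    """Fold and percent difference of each group vs control at one time point.

    Group means are taken across wells (each well's technical replicates
    are assumed already averaged into its row). The control group's fold is
    1 by construction.
    """
    df = add_index(series)
    at = df[np.isclose(df["time_h"].astype(float), at_time_h)]
    if at.empty:
        raise ValueError(f"no rows at time {at_time_h} h")
    if control_group not in set(at["group"]):
        raise ValueError(f"control group {control_group!r} absent at {at_time_h} h")
    means = at.groupby("group")["phagocytic_index"].agg(["mean", "count"])
    ctrl = float(means.loc[control_group, "mean"])
    if not np.isfinite(ctrl) or ctrl == 0:
        raise ValueError("control mean index is zero or undefined")
    out = []
    for group, row in means.iterrows():
        fold = float(row["mean"]) / ctrl
        out.append(
            GroupFold(
                group=str(group),
                fold=fold,
                percent_difference=100.0 * (fold - 1.0),
                mean_index=float(row["mean"]),
                n_wells=int(row["count"]),
            )
        )
    return out
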