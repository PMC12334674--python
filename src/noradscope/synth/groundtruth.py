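"""Ground-truth containers for the synthetic generators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["GroundTruth"]


@dataclass
class GroundTruth:
    """What a generator actually planted, for verification downstream.

    Only the fields relevant to a given generator are populated:

    - ``roi_labels``: tidy table (animal_id, fov_id, roi, label, amplitude)
      of planted per-ROI response classes;
    - ``true_area_fraction``: table (group, animal_id, slice_id, area_pct)
      of planted mask area fractions, %, recounted from the masks;
    - ``true_intersections``: mapping of sorted marker tuples to planted
      intersection volumes in µm³, voxel-recounted;
    - ``true_traj``: (n_frames, 3) true nose positions, cm;
    - ``group_params``: the population parameters of each simulated group.
    """

    roi_labels: pd.DataFrame | None = None
    roi_amplitudes: np.ndarray | None = None
    true_area_fraction: pd.DataFrame | None = None
    true_intersections: dict[tuple[str, ...], float] | None = None
    true_traj: np.ndarray | None = None
    group_params: dict[str, Any] = field(default_factory=dict)
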