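"""Histological area-fraction quantification.

Area % of an immunostain (fibres, microglia, plaques) per slice image,
optionally per anatomical-layer mask, averaged per animal, and relative
density / loss contrasts between groups. Binarisation reproduces the
threshold-based procedure: percentile intensity normalisation stands in for
manual brightness/contrast adjustment (which is not reproducible), followed
by Otsu's threshold; a fixed-threshold mode is provided for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

__all__ = [
    "HistoImage",
    "DensityRecord",
    "BinarizeResult",
    "binarize",
    "area_fraction",
    "animal_summary",
    "relative_loss",
    "layer_density",
    "count_objects",
]


@dataclass
class HistoImage:
    """A single 2D channel image with optional named region masks."""

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    channel: str = "NET"
    region_masks: dict[str, np.ndarray] = field(default_factory=dict)
    animal_id: str = "animal0"
    slice_id: str = "slice0"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D (y, x)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for name, m in self.region_masks.items():
            if np.shape(m) != self.pixels.shape:
                raise ValueError(f"region mask {name!r} does not match image shape")


@dataclass(frozen=True)
class DensityRecord:
    """One slice-level area-% measurement."""

    animal_id: str
    group: str
    value: float  # area %, in [0, 100]
    region: str = "whole"
    slice_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 100.0):
            raise ValueError(f"area % {self.value} outside [0, 100]")


@dataclass(frozen=True)
class BinarizeResult:
    mask: np.ndarray
    threshold: float
    method: str


def binarize(
    img: HistoImage | np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    normalize_percentiles: tuple[float, float] | None = (1.0, 99.0),
) -> BinarizeResult:
    """Threshold a stain image into a foreground mask.

    ``otsu`` rescales intensities to the given percentile range first (the
    reproducible stand-in for manual brightness/contrast adjustment) and
    applies Otsu's threshold; ``fixed`` uses ``fixed_threshold`` on the raw
    intensities. Foreground = pixels strictly above the threshold. The
    applied threshold is reported in the result.
    """
    pixels = np.asarray(img.pixels if isinstance(img, HistoImage) else img, float)
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        return BinarizeResult(pixels > fixed_threshold, float(fixed_threshold), "fixed")
    if method != "otsu":
        raise ValueError("method must be 'otsu' or 'fixed'")
    if np.ptp(pixels) == 0:
        raise ValueError("constant image: Otsu threshold undefined")
    work = pixels
    if normalize_percentiles is not None:
        lo, hi = np.percentile(pixels, normalize_percentiles)
        if hi > lo:
            work = np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)
    thr = float(filters.threshold_otsu(work))
    return BinarizeResult(work > thr, thr, "otsu")


def area_fraction(mask: np.ndarray, region: np.ndarray | None = None) -> float:
    """Foreground area % within ``region`` (whole image if None)."""
    mask = np.asarray(mask, bool)
    if region is None:
        region = np.ones_like(mask)
    region = np.asarray(region, bool)
    if region.shape != mask.shape:
        raise ValueError("region mask does not match image shape")
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")
    return 100.0 * int((mask & region).sum()) / n


def _records_frame(records: Sequence[DensityRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records])


def animal_summary(records: Sequence[DensityRecord] | pd.DataFrame) -> pd.DataFrame:
    """Mean area % per animal and region, averaging its slices."""
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no density records")
    out = (
        df.groupby(["group", "animal_id", "region"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean_value"})
    )
    return out


def relative_loss(
    case_means: Sequence[float], control_means: Sequence[float]
) -> tuple[float, float]:
    """(relative density %, loss %) of the case group vs the control group.

    Relative density = 100 x mean(case animal means) / mean(control animal
    means); loss = 100 - relative density.
    """
    case = np.asarray(case_means, float)
    control = np.asarray(control_means, float)
    if case.size == 0 or control.size == 0:
        raise ValueError("empty group")
    cm = control.mean()
    if cm <= 0:
        raise ValueError("control mean must be > 0")
    rel = 100.0 * case.mean() / cm
    return rel, 100.0 - rel


def layer_density(
    img: HistoImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    group: str = "",
) -> list[DensityRecord]:
    """Area % of the stain within each named layer mask of ``img``.

    Layers must be pairwise disjoint (anatomical layers do not overlap).
    """
    if not img.region_masks:
        raise ValueError("image has no layer masks")
    masks = {k: np.asarray(m, bool) for k, m in img.region_masks.items()}
    total = np.zeros(img.pixels.shape, int)
    for m in masks.values():
        total += m
    if (total > 1).any():
        raise ValueError("layer masks overlap")
    res = binarize(img, method=method, fixed_threshold=fixed_threshold)
    return [
        DensityRecord(
            animal_id=img.animal_id,
            group=group,
            value=area_fraction(res.mask, m),
            region=name,
            slice_id=img.slice_id,
        )
        for name, m in masks.items()
    ]


def count_objects(
    mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 0.0,
    connectivity: int = 2,
) -> int:
    """Count connected foreground objects (8-connectivity by default),
    discarding components smaller than ``min_area_um2``."""
    mask = np.asarray(mask, bool)
    min_px = int(np.ceil(min_area_um2 / (pixel_size_um**2))) if min_area_um2 else 0
    if min_px > 1:
        # drop components of fewer than min_px pixels
        mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    return int(measure.label(mask, connectivity=connectivity).max())
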