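"""Named simulation presets.

Each preset bundles every generator parameter for one study condition, so a
cohort is fully specified by ``(preset name, seed)``. Presets are frozen:
identical name and seed always produce bit-identical synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

__all__ = ["SimPreset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class SimPreset:
    """A named, seeded bundle of generator parameters."""

    name: str
    params: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def with_seed(self, seed: int | None) -> "SimPreset":
        """Return a copy with the seed replaced (None keeps the preset seed)."""
        if seed is None:
            return self
        return replace(self, seed=int(seed))

    def with_params(self, **overrides: Any) -> "SimPreset":
        return replace(self, params={**dict(self.params), **overrides})


_TWOP_COMMON = dict(
    n_animals=3,
    n_fovs=3,
    n_frames=203,          # ~3 min at 1.13 Hz
    height=120,
    width=120,
    n_z=8,                 # desk-scale stand-in for the 30-slice stack
    stim_frame=68,         # 1-based; 10 s air puff after ~1 min baseline
    frame_rate_hz=1.13,
    pixel_size_um=0.22,
    amp_inc=0.04,          # planted dF/F plateau amplitudes
    amp_dec=-0.04,
    noise_sd=0.005,        # per-pixel dF/F-scale noise sd
    vessel_tiles=3,        # dark (vessel-like) tiles per FOV
    grid_rows=6,
    grid_cols=6,
)

_FIBER_COMMON = dict(
    control_mean=12.0,     # control area fraction %, Normal(12, 1) per slice
    control_sd=1.0,
    n_animals=5,
    n_slices=4,
    shape=(256, 256),
    fibre_width=3,
    noise_sd=6.0,
    pixel_size_um=0.4,
)

PRESETS: dict[str, SimPreset] = {
    p.name: p
    for p in [
        # Control-like cohort: 75% of ROIs respond with an increase, 5% with
        # a decrease, matching the wild-type response fractions.
        SimPreset("wt_fig2", {**_TWOP_COMMON, "p_inc": 0.75, "p_dec": 0.05}, seed=42),
        # Amyloidosis-like cohort with blunted release.
        SimPreset("app_fig2", {**_TWOP_COMMON, "p_inc": 0.40, "p_dec": 0.15}, seed=43),
        # Fibre-density loss time course: case area fractions scaled to give
        # 14/27/33% loss at 2/3/6 months.
        SimPreset("fiberloss_2m", {**_FIBER_COMMON, "case_scale": 0.86}, seed=202),
        SimPreset("fiberloss_3m", {**_FIBER_COMMON, "case_scale": 0.73}, seed=203),
        SimPreset("fiberloss_6m", {**_FIBER_COMMON, "case_scale": 0.67}, seed=206),
        # LC-restricted transgene expression: 15% loss, 3 slices per animal.
        SimPreset(
            "dbh_app", {**_FIBER_COMMON, "case_scale": 0.85, "n_slices": 3}, seed=207
        ),
        # Buried-food latencies: control ~40 s, case 60% slower.
        SimPreset(
            "buriedfood_3m",
            dict(mean_control=40.0, ratio=1.60, n_control=14, n_case=18, cv=0.30),
            seed=314,
        ),
        # Phagocytic-uptake time course: case index 1.33-fold control at 12 h.
        SimPreset(
            "phago_12h",
            dict(
                plateau_control=20.0,
                fold=1.33,
                timepoints=tuple(range(0, 25)),
                noise_cv=0.10,
                n_wells=12,
                include_cytod=True,
            ),
            seed=128,
        ),
    ]
}


def get_preset(name: str, seed: int | None = None) -> SimPreset:
    """Look up a preset by name, optionally overriding its seed."""
    try:
        preset = PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; known presets: {known}") from None
    return preset.with_seed(seed)
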