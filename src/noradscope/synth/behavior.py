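"""Synthetic tracked-nose sessions and buried-food latency cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._sampling import stratified_lognormal
from ..presets import SimPreset
from .groundtruth import GroundTruth

__all__ = ["gen_behavior_session", "gen_latencies"]


def gen_behavior_session(
    attraction: float = 0.0,
    duration_s: float = 300.0,
    fps: float = 30.0,
    tip: tuple[float, float, float] = (10.0, 10.0, 5.0),
    seed: int | np.random.SeedSequence = 0,
    box_cm: tuple[float, float, float] = (20.0, 20.0, 20.0),
    step_sd_cm: float = 0.5,
    jitter_sd_cm: float = 0.0,
    start: tuple[float, float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a nose trajectory and its two orthogonal camera views.

    The true trajectory is a reflected random walk in a box; ``attraction``
    adds a drift of that many step standard deviations toward the fixed
    odour tip (0 = pure random walk). The top view records (frame, x, y)
    and the side view (frame, x, z), exact orthogonal projections plus
    optional Gaussian jitter, in cm.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if attraction < 0:
        raise ValueError("attraction must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    box = np.asarray(box_cm, float)
    tip_arr = np.asarray(tip, float)

    pos = np.empty((n, 3))
    cur = np.asarray(start, float) if start is not None else box / 2.0
    for i in range(n):
        step = rng.normal(0.0, step_sd_cm, 3)
        to_tip = tip_arr - cur
        dist = np.linalg.norm(to_tip)
        if attraction > 0 and dist > 1e-9:
            step += attraction * step_sd_cm * to_tip / dist
        cur = cur + step
        # reflect back into the box
        for ax in range(3):
            if cur[ax] < 0:
                cur[ax] = -cur[ax]
            if cur[ax] > box[ax]:
                cur[ax] = 2 * box[ax] - cur[ax]
            cur[ax] = np.clip(cur[ax], 0, box[ax])
        pos[i] = cur

    frames = np.arange(n)
    jit = lambda: rng.normal(0.0, jitter_sd_cm, n) if jitter_sd_cm > 0 else 0.0
    top = pd.DataFrame({"frame": frames, "x": pos[:, 0] + jit(), "y": pos[:, 1] + jit()})
    side = pd.DataFrame({"frame": frames, "x": pos[:, 0] + jit(), "z": pos[:, 2] + jit()})
    gt = GroundTruth(
        true_traj=pos,
        group_params=dict(
            attraction=attraction,
            step_sd_cm=step_sd_cm,
            jitter_sd_cm=jitter_sd_cm,
            tip=tuple(tip_arr),
            fps=fps,
        ),
    )
    return top, side, gt


def gen_latencies(
    mean_control: float = 40.0,
    ratio: float = 1.60,
    n_control: int = 14,
    n_case: int = 18,
    cv: float = 0.30,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Buried-food latency table for a control and a case group.

    Latencies are lognormal with the given arithmetic means and coefficient
    of variation; the case population mean is ``mean_control x ratio``.
    Values are drawn by stratified sampling so the small groups track their
    population means.
    """
    if mean_control <= 0 or ratio <= 0:
        raise ValueError("means must be > 0")
    if n_control < 2 or n_case < 2:
        raise ValueError("group sizes must be >= 2")
    root = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    s1, s2 = root.spawn(2)
    control = stratified_lognormal(
        np.random.default_rng(s1), n_control, mean_control, cv
    )
    case = stratified_lognormal(
        np.random.default_rng(s2), n_case, mean_control * ratio, cv
    )
    df = pd.DataFrame(
        {
            "group": ["control"] * n_control + ["case"] * n_case,
            "animal_id": [f"c{i}" for i in range(n_control)]
            + [f"a{i}" for i in range(n_case)],
            "latency_s": np.concatenate([control, case]),
        }
    )
    gt = GroundTruth(
        group_params=dict(
            mean_control=mean_control,
            mean_case=mean_control * ratio,
            ratio=ratio,
            cv=cv,
        )
    )
    return df, gt


def gen_latencies_from_preset(preset: SimPreset):
    p = dict(preset.params)
    return gen_latencies(
        mean_control=float(p["mean_control"]),
        ratio=float(p["ratio"]),
        n_control=int(p["n_control"]),
        n_case=int(p["n_case"]),
        cv=float(p["cv"]),
        seed=preset.seed,
    )
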