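"""Variance-controlled sampling helpers for small synthetic cohorts.

The generators emulate group contrasts measured on a handful of animals or
wells. Plain iid draws at those sizes scatter group means far from their
population values; jittered stratified (quantile) sampling keeps each tiny
sample representative of its distribution while remaining random and
seed-deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["stratified_normal", "stratified_lognormal", "lognormal_params"]


def _stratified_uniforms(rng: np.random.Generator, n: int) -> np.ndarray:
    """One uniform draw per equal-probability stratum, in shuffled order."""
    u = (np.arange(n) + rng.random(n)) / n
    rng.shuffle(u)
    return u


def stratified_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    """Draw ``n`` Normal(mean, sd) values by jittered stratified sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return np.full(n, float(mean))
    return mean + sd * stats.norm.ppf(_stratified_uniforms(rng, n))


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of the log for a lognormal with given mean and CV."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def stratified_lognormal(
    rng: np.random.Generator, n: int, mean: float, cv: float
) -> np.ndarray:
    """Draw ``n`` lognormal values with the given arithmetic mean and CV."""
    mu, sigma = lognormal_params(mean, cv)
    if sigma == 0:
        return np.full(n, float(mean))
    return np.exp(mu + sigma * stats.norm.ppf(_stratified_uniforms(rng, n)))
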