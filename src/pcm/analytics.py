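"""Collision and amplification probability analysis.

For rotationally invariant (Gaussian) hyperplanes, two vectors at angle
theta receive equal sign bits with probability 1 - theta/pi.  A table
matches only when all r*c bits agree (probability p^(r*c) under
independence), and the method declares similarity on a match in any of
k tables, so the overall match probability is

    P(match) = 1 - (1 - p^(r*c))^k,

the AND-OR amplification curve that trades false negatives against
false positives.  The closed form is exact only in gaussian mode;
uniform(-1, 1) hyperplanes are validated by Monte-Carlo
self-consistency instead.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .lsh import ConfigurationError, LSHConfig


def bit_collision_prob(theta: float | np.ndarray) -> float | np.ndarray:
    """P(two vectors at angle theta get the same bit) = 1 - theta/pi."""
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr < 0) or np.any(theta_arr > math.pi):
        raise ValueError("theta must lie in [0, pi]")
    out = 1.0 - theta_arr / math.pi
    return float(out) if np.isscalar(theta) or theta_arr.ndim == 0 else out


def overall_match_prob(
    p_bit: float | np.ndarray, c: int, r: int, k: int
) -> float | np.ndarray:
    """P(full-key match in at least one of k tables) given per-bit p."""
    for name, v in (("c", c), ("r", r), ("k", k)):
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
    p = np.asarray(p_bit, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_bit must lie in [0, 1]")
    out = 1.0 - (1.0 - p ** (c * r)) ** k
    return float(out) if np.isscalar(p_bit) or p.ndim == 0 else out


def amplification_curve(
    c: int, r: int, k: int, angle_grid: np.ndarray | int = 50
) -> pd.DataFrame:
    """Per-bit / per-table / overall match probability over an angle grid.

    ``angle_grid`` is either an array of angles in radians or a point
    count for an even grid on [0, pi].
    """
    if isinstance(angle_grid, (int, np.integer)):
        grid = np.linspace(0.0, math.pi, int(angle_grid))
    else:
        grid = np.asarray(angle_grid, dtype=float)
    per_bit = bit_collision_prob(grid)
    per_bit = np.atleast_1d(per_bit)
    per_table = per_bit ** (c * r)
    overall = np.atleast_1d(overall_match_prob(per_bit, c, r, k))
    return pd.DataFrame(
        {"theta": grid, "per_bit": per_bit, "per_table": per_table, "overall": overall}
    )


def empirical_collision_prob(
    v1: np.ndarray,
    v2: np.ndarray,
    config: LSHConfig,
    n_trials: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the any-table match event, with its SE.

    Each trial draws a fresh bank of k*r*c hyperplanes from the
    configured distribution and tests whether the two vectors share a
    full index key in at least one table.  Returns (estimate, binomial
    standard error).
    """
    if n_trials < 100:
        raise ValueError("n_trials must be at least 100")
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("v1 and v2 must be 1-D vectors of equal length")
    n = v1.shape[0]
    rng = np.random.default_rng(seed)
    bits_per_table = config.r * config.c
    total_planes = n_trials * config.k * bits_per_table
    if config.hyperplane_distribution == "uniform":
        planes = rng.uniform(-1.0, 1.0, size=(total_planes, n))
    else:
        planes = rng.standard_normal(size=(total_planes, n))
    b1 = (planes @ v1 > 0.0).reshape(n_trials, config.k, bits_per_table)
    b2 = (planes @ v2 > 0.0).reshape(n_trials, config.k, bits_per_table)
    table_match = np.all(b1 == b2, axis=2)
    any_match = np.any(table_match, axis=1)
    est = float(any_match.mean())
    se = math.sqrt(est * (1.0 - est) / n_trials)
    return est, se
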