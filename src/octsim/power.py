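"""Z-score sample-size determination and the classical (model-free) baseline.

The detection criterion is ``z = delta / sqrt(se1^2 + se2^2) >= 1.96`` (95%
two-sided), where delta is the between-arm difference in mean endpoint CST
and se1/se2 are the per-arm endpoint standard errors at a given per-arm
sample size N.  ``n_star`` is the smallest grid N reaching the criterion.

In the classical setting the SEs come from bootstrapping the arithmetic mean
of individually simulated endpoint values; in the model-based settings they
come from the bootstrap-plus-Monte-Carlo propagation chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Z_THRESHOLD", "PowerCurve", "z_score", "classical_se", "find_n_star"]

#: 95% two-sided detection threshold.
Z_THRESHOLD = 1.96


def z_score(delta: float, se1: float, se2: float) -> float:
    """``delta / sqrt(se1^2 + se2^2)``; undefined when both SEs vanish."""
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    denom = np.hypot(se1, se2)
    if denom == 0:
        raise ZeroDivisionError("z-score undefined: both standard errors are zero")
    return float(delta / denom)


def classical_se(
    pool_endpoints: np.ndarray,
    n: int,
    boot_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    outer_reps: int = 200,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap SE of the mean of ``n`` endpoint values drawn from the pool.

    The point SE is the SD of ``boot_reps`` resampled means.  The (2.5, 97.5)
    band repeats the SE estimate on ``outer_reps`` resampled pools.
    """
    pool = np.asarray(pool_endpoints, float)
    if boot_reps < 2:
        raise ValueError("boot_reps must be at least 2")
    if pool.size == 0:
        raise ValueError("empty endpoint pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.ptp(pool) == 0.0:
        return 0.0, (0.0, 0.0)
    means = rng.choice(pool, size=(boot_reps, n), replace=True).mean(axis=1)
    se = float(means.std(ddof=1))
    if outer_reps <= 0:
        return se, (se, se)
    outer = np.empty(outer_reps)
    for b in range(outer_reps):
        repool = rng.choice(pool, size=pool.size, replace=True)
        m = rng.choice(repool, size=(boot_reps, n), replace=True).mean(axis=1)
        outer[b] = m.std(ddof=1)
    band = (float(np.percentile(outer, 2.5)), float(np.percentile(outer, 97.5)))
    return se, (min(band[0], se), max(band[1], se))


@dataclass
class PowerCurve:
    """Per-N z-scores with quantile ribbons and the threshold crossing."""

    n_grid: np.ndarray
    z: np.ndarray
    z_band: np.ndarray  # (len(n), 2): z from the 97.5th / 2.5th SE quantiles
    n_star: int | None  # smallest grid N with z >= 1.96 (None: not reached)
    n_star_band: tuple[int | None, int | None]  # crossings of the two band curves
    max_z: float

    @property
    def reached(self) -> bool:
        return self.n_star is not None


def _first_crossing(n_grid: np.ndarray, z: np.ndarray) -> int | None:
    hits = np.nonzero(z >= Z_THRESHOLD)[0]
    return int(n_grid[hits[0]]) if hits.size else None


def find_n_star(
    n_grid: np.ndarray,
    delta: np.ndarray | float,
    se1: np.ndarray,
    se2: np.ndarray,
    se1_band: np.ndarray | None = None,
    se2_band: np.ndarray | None = None,
) -> PowerCurve:
    """Assemble the z-curve over the N grid and locate the 1.96 crossing.

    ``delta`` may be a scalar or per-N vector; band arrays hold per-N
    (2.5th, 97.5th) SE quantiles.  No interpolation: crossings are reported
    at grid values.  The optimistic band z uses the 2.5th-quantile SEs, the
    pessimistic one the 97.5th.
    """
    n_grid = np.asarray(n_grid)
    if np.any(np.diff(n_grid) <= 0):
        raise ValueError("n_grid must be strictly increasing")
    se1 = np.asarray(se1, float)
    se2 = np.asarray(se2, float)
    delta_arr = np.broadcast_to(np.asarray(delta, float), n_grid.shape)
    z = np.array([z_score(d, a, b) for d, a, b in zip(delta_arr, se1, se2)])

    if se1_band is None or se2_band is None:
        z_hi = z_lo = z
    else:
        b1 = np.asarray(se1_band, float)
        b2 = np.asarray(se2_band, float)
        z_hi = np.array(
            [z_score(d, a, b) for d, a, b in zip(delta_arr, b1[:, 0], b2[:, 0])]
        )
        z_lo = np.array(
            [z_score(d, a, b) for d, a, b in zip(delta_arr, b1[:, 1], b2[:, 1])]
        )
    n_star = _first_crossing(n_grid, z)
    n_hi = _first_crossing(n_grid, z_hi)  # optimistic: crosses at smaller N
    n_lo = _first_crossing(n_grid, z_lo)
    return PowerCurve(
        n_grid=n_grid,
        z=z,
        z_band=np.column_stack([z_hi, z_lo]),
        n_star=n_star,
        n_star_band=(n_hi, n_lo),
        max_z=float(z.max()),
    )
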