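"""End-to-end sample-size workflows over the simulation/fitting machinery.

These functions chain cohort simulation, bootstrap refitting, Monte Carlo
propagation and the z-score criterion into the three monitoring settings
compared in the study design analysis:

  classical — endpoint SEs from bootstrapping the arithmetic mean of
      individually simulated week-44 CST values (no model);
  onsite / home — endpoint SEs from case-resampling bootstrap refits of the
      population model on sparsely / densely sampled data, propagated to the
      model-implied arm-mean endpoint.

The model-based standard-error curve is evaluated by direct bootstrap at a
small set of anchor sample sizes and carried across the n grid with the
asymptotic 1/sqrt(n) law, which the anchor estimates themselves are checked
against in the test suite.  This keeps the desk-scale run tractable; the
full per-n bootstrap is a matter of passing a denser ``anchors`` grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import ObservationDataset, TrialDesign
from .params import PopulationParameters
from .power import PowerCurve, classical_se, find_n_star
from .uncertainty import bootstrap_fits, propagate_endpoint

__all__ = ["SettingResult", "classical_setting", "model_based_setting"]


@dataclass
class SettingResult:
    """Power curve of one monitoring setting plus its ingredients."""

    setting: str
    curve: PowerCurve
    delta: float  # µm
    se_per_arm: dict[str, np.ndarray]  # per grid n
    band_per_arm: dict[str, np.ndarray] | None  # per grid n, (lo, hi)
    detail: dict


def classical_setting(
    pool: ObservationDataset,
    endpoint_day: float,
    n_grid: np.ndarray,
    boot_reps: int = 1000,
    seed: int | None = None,
    outer_reps: int = 200,
) -> SettingResult:
    """Classical statistical baseline on a simulated two-arm endpoint pool."""
    rng = np.random.default_rng(seed)
    arms = pool.arms
    endpoints = {arm: pool.endpoint_values(endpoint_day, arm) for arm in arms}
    if len(arms) != 2:
        raise ValueError("classical_setting expects a two-arm pool")
    ref, trial = arms[0], arms[1]
    # convention: delta = comparator mean - trial-drug mean (positive effect)
    delta = float(endpoints[ref].mean() - endpoints[trial].mean())
    if delta < 0:
        ref, trial = trial, ref
        delta = -delta
    ses, bands = {}, {}
    for arm in (trial, ref):
        se_list, band_list = [], []
        for n in n_grid:
            se, band = classical_se(endpoints[arm], int(n), boot_reps, rng, outer_reps)
            se_list.append(se)
            band_list.append(band)
        ses[arm] = np.array(se_list)
        bands[arm] = np.array(band_list)
    curve = find_n_star(n_grid, delta, ses[trial], ses[ref], bands[trial], bands[ref])
    return SettingResult(
        setting="classical",
        curve=curve,
        delta=delta,
        se_per_arm=ses,
        band_per_arm=bands,
        detail={"endpoints": endpoints},
    )


def model_based_setting(
    pool: ObservationDataset,
    design: TrialDesign,
    pop: PopulationParameters,
    setting: str,
    n_grid: np.ndarray,
    anchors: tuple[int, ...] = (24, 48),
    reps: int = 24,
    n_mc: int = 500,
    seed: int | None = None,
    outer_reps: int = 0,
    statistic: str = "mean",
) -> SettingResult:
    """Bootstrap-plus-Monte-Carlo power curve for one monitoring setting.

    ``pool`` must be the two-arm dataset simulated under the setting's
    sampling schedule.  Per arm, the endpoint SE is estimated by refitting
    ``reps`` case-resamples at each anchor size and propagating the estimate
    ensemble to the model-implied mean endpoint; the SE curve over
    ``n_grid`` follows 1/sqrt(n) through the pooled anchor estimates.

    The z-test effect size is the pool's observed arm-mean difference — the
    same estimator the classical baseline uses (the model-implied Monte
    Carlo means, kept in ``detail``, are far too noisy at desk-scale
    replicate counts to serve as a Δ estimate).
    """
    rng = np.random.default_rng(seed)
    drug_by_arm = {arm_id: drug for arm_id, drug, _ in design.arms}
    ses, bands, deltas, detail = {}, {}, {}, {"anchor_se": {}, "ensembles": {}}
    for arm_id in pool.arms:
        drug = drug_by_arm[arm_id]
        arm_pop = design.arm_population(pop, arm_id)
        arm_pool = pool.for_arm(arm_id)
        a_sq, anchor_se, means = [], {}, []
        band_ratio = None
        for n in anchors:
            ens = bootstrap_fits(
                arm_pool, int(n), reps, drug, arm_pop, seed=int(rng.integers(2**31))
            )
            dist = propagate_endpoint(
                ens,
                design,
                drug,
                n_mc=n_mc,
                seed=int(rng.integers(2**31)),
                outer_reps=outer_reps if n == anchors[-1] else 0,
                init=arm_pop,
                statistic=statistic,
            )
            anchor_se[int(n)] = dist.se
            a_sq.append(dist.se**2 * n)
            means.append(dist.mean)
            if n == anchors[-1] and outer_reps > 0:
                band_ratio = (
                    dist.quantile_band[0] / dist.se if dist.se > 0 else 1.0,
                    dist.quantile_band[1] / dist.se if dist.se > 0 else 1.0,
                )
            detail["ensembles"].setdefault(arm_id, {})[int(n)] = ens
        a = float(np.sqrt(np.mean(a_sq)))
        ses[arm_id] = a / np.sqrt(n_grid)
        if band_ratio is not None:
            bands[arm_id] = np.column_stack(
                [ses[arm_id] * band_ratio[0], ses[arm_id] * band_ratio[1]]
            )
        deltas[arm_id] = float(np.mean(means))
        detail["anchor_se"][arm_id] = anchor_se
    detail["mc_means"] = dict(deltas)
    arms = pool.arms
    ref, trial = arms[0], arms[1]
    pool_means = {
        arm: float(pool.endpoint_values(design.endpoint_day, arm).mean()) for arm in arms
    }
    delta = pool_means[ref] - pool_means[trial]
    if delta < 0:
        ref, trial = trial, ref
        delta = -delta
    curve = find_n_star(
        n_grid,
        delta,
        ses[trial],
        ses[ref],
        bands.get(trial),
        bands.get(ref),
    )
    return SettingResult(
        setting=setting,
        curve=curve,
        delta=delta,
        se_per_arm=ses,
        band_per_arm=bands if bands else None,
        detail=detail,
    )
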