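"""Bootstrap-over-patients uncertainty and Monte Carlo endpoint propagation.

From a large simulated patient pool, N patients are drawn with replacement
and the population model is refitted; repeating this yields an empirical
sampling distribution of the fixed effects.  Parameter uncertainty is then
propagated to the week-44 endpoint by sampling fixed-effect vectors from the
ensemble's log-scale covariance and simulating the typical (eta = 0)
trajectory under the arm's regimen; the SD of the simulated endpoint values
is the model-based standard error of the endpoint.

Quantile ribbons on that SE come from an outer bootstrap over the replicate
estimate set (resample the fitted theta vectors, recompute covariance and
re-propagate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .cohort import ObservationDataset, TrialDesign, simulate_trial
from .estimation import FitResult, fit_population
from .params import DrugSpec, PopulationParameters

__all__ = [
    "BootstrapEnsemble",
    "EndpointDistribution",
    "generate_pool",
    "bootstrap_fits",
    "propagate_endpoint",
]


def generate_pool(
    pop: PopulationParameters,
    design: TrialDesign,
    mode: str = "home",
    pool_size: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ObservationDataset:
    """Simulate the bootstrap source population: ``pool_size`` patients per arm."""
    sized = TrialDesign(
        arms=design.arms,
        run_in_doses=design.run_in_doses,
        arm_doses=design.arm_doses,
        endpoint_day=design.endpoint_day,
        n_per_arm=pool_size,
    )
    return simulate_trial(pop, sized, mode=mode, seed=seed)


@dataclass
class BootstrapEnsemble:
    """Fits of resampled datasets and their log-scale moments."""

    n_patients: int
    replicates: list[FitResult]
    theta_names: tuple[str, ...]
    theta_matrix: np.ndarray  # (n_converged, n_free) log-scale estimates
    theta_mean: np.ndarray
    theta_cov: np.ndarray
    n_failed: int
    unreliable: bool


def bootstrap_fits(
    pool: ObservationDataset,
    n: int,
    reps: int,
    drug: DrugSpec,
    init: PopulationParameters,
    seed: int | None = None,
    fixed: frozenset[str] | set[str] = frozenset(),
    **fit_kwargs,
) -> BootstrapEnsemble:
    """Case-resampling bootstrap: draw ``n`` patients with replacement from a
    single-arm pool, refit, repeat ``reps`` times.

    Duplicated patients are relabelled so the fitter treats them as distinct
    subjects.  Failed fits are dropped (never imputed); the ensemble is
    flagged unreliable if more than half fail.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if reps < 2:
        raise ValueError("reps must be at least 2")
    rng = np.random.default_rng(seed)
    ids = pool.patient_ids()
    results: list[FitResult] = []
    n_failed = 0
    for _ in range(reps):
        chosen = rng.choice(ids, size=n, replace=True)
        resampled = pool.subset(chosen, relabel=True)
        try:
            fit = fit_population(resampled, drug, init, fixed=fixed, **fit_kwargs)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        if fit.converged and np.isfinite(fit.ofv):
            results.append(fit)
        else:
            n_failed += 1
    if not results:
        raise RuntimeError("every bootstrap replicate failed to fit")
    theta_names = results[0].free_names
    mat = np.array([r.theta_vector() for r in results])
    cov = np.cov(mat, rowvar=False) if mat.shape[0] > 1 else np.zeros((mat.shape[1],) * 2)
    unreliable = n_failed > reps / 2
    if unreliable:
        warnings.warn(
            f"bootstrap ensemble unreliable: {n_failed}/{reps} fits failed", RuntimeWarning
        )
    return BootstrapEnsemble(
        n_patients=n,
        replicates=results,
        theta_names=theta_names,
        theta_matrix=mat,
        theta_mean=mat.mean(axis=0),
        theta_cov=np.atleast_2d(cov),
        n_failed=n_failed,
        unreliable=unreliable,
    )


@dataclass
class EndpointDistribution:
    """Monte Carlo distribution of the typical endpoint CST."""

    samples: np.ndarray  # µm
    se: float  # µm, SD of samples
    quantile_band: tuple[float, float]  # (2.5th, 97.5th) of outer-bootstrap SEs
    mean: float  # µm


def _nearest_psd(cov: np.ndarray) -> tuple[np.ndarray, bool]:
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    if vals.min() >= 0:
        return cov, False
    clipped = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    return clipped, True


def _sample_mvn(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray, size: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((size, mean.size))
    return mean + z @ root.T


def _param_layout(theta_names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Map free-parameter names to kernel slots.

    kind 0: structural log parameter (index into the 7-vector);
    kind 1: log random-effect variance (index into the effect vector);
    kind 2: ignored by trajectory simulation (log sigma).
    """
    from .estimation import _LP_NAMES
    from .params import RANDOM_EFFECTS

    lp_idx = {n: i for i, n in enumerate(_LP_NAMES)}
    om_idx = {f"omega_{k}": i for i, k in enumerate(RANDOM_EFFECTS)}
    kind = np.empty(len(theta_names), dtype=np.int64)
    target = np.zeros(len(theta_names), dtype=np.int64)
    for j, name in enumerate(theta_names):
        if name in lp_idx:
            kind[j], target[j] = 0, lp_idx[name]
        elif name in om_idx:
            kind[j], target[j] = 1, om_idx[name]
        else:
            kind[j] = 2
    return kind, target


def _endpoint_statistic(
    samples: np.ndarray,
    kind: np.ndarray,
    target: np.ndarray,
    base_lp: np.ndarray,
    base_logom: np.ndarray,
    z: np.ndarray,
    kel: float,
    dose_t: np.ndarray,
    dose_a: np.ndarray,
    endpoint_day: float,
) -> np.ndarray:
    out = _kernels.mc_mean_endpoints(
        samples, kind, target, base_lp, base_logom, z, kel, dose_t, dose_a,
        endpoint_day, 1.0e-6, 1.0e-6,
    )
    if np.any(np.isnan(out)):
        raise RuntimeError("endpoint simulation failed for a sampled parameter set")
    return out


def propagate_endpoint(
    ensemble: BootstrapEnsemble,
    design: TrialDesign,
    drug: DrugSpec,
    n_mc: int = 1000,
    seed: int | None = None,
    outer_reps: int = 200,
    init: PopulationParameters | None = None,
    statistic: str = "mean",
    iiv_draws: int = 64,
    band_n_mc: int | None = None,
) -> EndpointDistribution:
    """Propagate fitted-parameter uncertainty to the endpoint-day CST.

    Draws ``n_mc`` parameter vectors from a log-scale multivariate normal
    with the ensemble's mean and covariance (projected to the nearest PSD
    matrix if needed, with a warning) and evaluates, for each, the
    model-implied *population-mean* CST at the endpoint day under the arm's
    full regimen — the arm-mean being the quantity the z-test compares across
    monitoring settings.  The mean marginalizes inter-individual variability
    with ``iiv_draws`` standard-normal draws shared across all parameter
    vectors (so finite-draw noise cancels out of the spread).  The SE is the
    SD of the resulting endpoint statistics.  ``statistic="typical"``
    propagates through the eta = 0 trajectory instead (no IIV marginal).

    The (2.5, 97.5) band re-propagates ``outer_reps`` outer bootstrap
    resamples of the replicate estimate set, each with ``band_n_mc``
    parameter draws (default: n_mc capped at 200).
    """
    if statistic not in ("mean", "typical"):
        raise ValueError("statistic must be 'mean' or 'typical'")
    rng = np.random.default_rng(seed)
    cov, adjusted = _nearest_psd(ensemble.theta_cov)
    if adjusted:
        warnings.warn("ensemble covariance projected to nearest PSD", RuntimeWarning)

    base_pop = init if init is not None else ensemble.replicates[0].theta_hat
    from .estimation import _pop_to_lp

    base_lp = _pop_to_lp(base_pop, drug)
    base_logom = np.log(np.maximum(base_pop.omega_vector(), 1.0e-300))
    doses = design.all_doses
    dose_t = np.array([d.time for d in doses])
    dose_a = np.array([d.amount for d in doses])
    kind, target = _param_layout(ensemble.theta_names)
    z = (
        rng.standard_normal((iiv_draws, 5))
        if statistic == "mean"
        else np.empty((0, 5))
    )

    def run(mat_mean: np.ndarray, mat_cov: np.ndarray, size: int) -> np.ndarray:
        draws = _sample_mvn(rng, mat_mean, mat_cov, size)
        return _endpoint_statistic(
            draws, kind, target, base_lp, base_logom, z, drug.k_el, dose_t,
            dose_a, design.endpoint_day,
        )

    samples = run(ensemble.theta_mean, cov, n_mc)
    se = float(np.std(samples, ddof=1)) if n_mc > 1 else 0.0

    mat = ensemble.theta_matrix
    if band_n_mc is None:
        band_n_mc = min(n_mc, 200)
    outer_ses = np.empty(outer_reps)
    for b in range(outer_reps):
        take = rng.integers(0, mat.shape[0], size=mat.shape[0])
        sub = mat[take]
        sub_cov, _ = _nearest_psd(np.atleast_2d(np.cov(sub, rowvar=False)))
        outer_ses[b] = np.std(run(sub.mean(axis=0), sub_cov, band_n_mc), ddof=1)
    if outer_reps > 0:
        band = (float(np.percentile(outer_ses, 2.5)), float(np.percentile(outer_ses, 97.5)))
        band = (min(band[0], se), max(band[1], se))
    else:
        band = (se, se)

    # a stable point estimate of the statistic itself (for the z-test delta)
    point = _endpoint_statistic(
        ensemble.theta_mean[None, :], kind, target, base_lp, base_logom,
        rng.standard_normal((4000, 5)) if statistic == "mean" else np.empty((0, 5)),
        drug.k_el, dose_t, dose_a, design.endpoint_day,
    )
    return EndpointDistribution(
        samples=samples, se=se, quantile_band=band, mean=float(point[0])
    )
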