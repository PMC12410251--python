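"""Approximate population-likelihood fitting, multistart and profiles.

The marginal likelihood over the random effects is approximated by a Laplace
expansion around per-patient conditional modes with a Gauss-Newton curvature
term (first-order conditional flavour).  The outer problem maximises it over
the log-scale fixed effects, log random-effect variances and log residual SD
with a quasi-Newton optimizer whose rounds are interleaved with closed-form
EM updates of the random-effect locations, variances and the residual SD —
directions whose likelihood is too flat for line searches to resolve.
Conditional modes restart from a fixed per-fit reference (refreshed at
accepted iterates) so the objective is deterministic.

Only single-drug datasets are fitted (each trial arm is fitted on its own);
the absent drug's potency is excluded from estimation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _kernels
from .cohort import ObservationDataset
from .params import RANDOM_EFFECTS, DrugSpec, PopulationParameters

__all__ = [
    "FitResult",
    "LikelihoodProfile",
    "fit_population",
    "multistart",
    "profile_likelihood",
    "predictions",
]

#: Structural parameters in the order of the individual log-parameter vector.
_LP_NAMES = ("cst_del", "kin", "ec50", "cst_min", "cst0", "pk0", "h")
#: All estimable parameter names (theta short names, omegas, sigma).
PARAM_NAMES = tuple(_LP_NAMES) + tuple(f"omega_{k}" for k in RANDOM_EFFECTS) + ("sigma",)

INNER_TOL = 1.0e-8
#: Outer gradient tolerance, per patient (the objective is normalized).
OUTER_GTOL = 0.01
#: Integrator tolerances on the fitting path; looser than the simulation
#: default (trajectory error ~1e-3 µm, three orders below the residual SD).
FIT_RTOL = 1.0e-5
FIT_ATOL = 1.0e-5
_OMEGA_FLOOR = 1.0e-8
_THETA_HALF_WIDTH = 3.0
_LOG_OMEGA_BOUNDS = (math.log(1.0e-4), math.log(50.0))
_LOG_SIGMA_BOUNDS = (math.log(0.5), math.log(100.0))


@dataclass
class _Packed:
    """Flat per-patient event arrays for the kernels."""

    ids: np.ndarray
    obs_y: np.ndarray
    obs_t: np.ndarray
    obs_off: np.ndarray
    dose_t: np.ndarray
    dose_a: np.ndarray
    dose_off: np.ndarray
    n_obs_total: int


def _pack(dataset: ObservationDataset) -> _Packed:
    df = dataset.df
    ids = np.sort(df["ID"].unique())
    obs_y, obs_t, dose_t, dose_a = [], [], [], []
    obs_off, dose_off = [0], [0]
    for pid in ids:
        block = df[df["ID"] == pid].sort_values(["TIME", "EVID"], ascending=[True, False])
        o = block[block["EVID"] == 0]
        d = block[block["EVID"] == 1]
        obs_y.append(o["DV"].to_numpy(float))
        obs_t.append(o["TIME"].to_numpy(float))
        dose_t.append(d["TIME"].to_numpy(float))
        dose_a.append(d["AMT"].to_numpy(float))
        obs_off.append(obs_off[-1] + len(o))
        dose_off.append(dose_off[-1] + len(d))
    return _Packed(
        ids=ids,
        obs_y=np.concatenate(obs_y) if obs_y else np.empty(0),
        obs_t=np.concatenate(obs_t) if obs_t else np.empty(0),
        obs_off=np.array(obs_off, dtype=np.int64),
        dose_t=np.concatenate(dose_t) if dose_t else np.empty(0),
        dose_a=np.concatenate(dose_a) if dose_a else np.empty(0),
        dose_off=np.array(dose_off, dtype=np.int64),
        n_obs_total=int(sum(len(a) for a in obs_y)),
    )


def _pop_to_lp(pop: PopulationParameters, drug: DrugSpec) -> np.ndarray:
    """Typical individual log parameters for one drug.

    Drugs other than ranibizumab (aflibercept and the aflibercept-like trial
    drug) read and write the aflibercept potency slot."""
    ec50 = (
        pop.theta_ec50_ranibizumab
        if drug.name == "ranibizumab"
        else pop.theta_ec50_aflibercept
    )
    return np.array(
        [
            pop.theta_cst_del,
            pop.theta_kin,
            ec50,
            pop.theta_cst_min,
            pop.theta_cst0,
            pop.theta_pk0,
            pop.theta_h,
        ]
    )


def _lp_to_pop(lp: np.ndarray, omega: np.ndarray, sigma: float, init: PopulationParameters, drug: DrugSpec) -> PopulationParameters:
    kwargs = dict(
        theta_cst_del=lp[0],
        theta_kin=lp[1],
        theta_cst_min=lp[3],
        theta_cst0=lp[4],
        theta_pk0=lp[5],
        theta_h=lp[6],
        sigma=sigma,
        omega=dict(zip(RANDOM_EFFECTS, (float(v) for v in omega))),
    )
    if drug.name == "ranibizumab":
        kwargs["theta_ec50_ranibizumab"] = lp[2]
        kwargs["theta_ec50_aflibercept"] = init.theta_ec50_aflibercept
    else:
        kwargs["theta_ec50_aflibercept"] = lp[2]
        kwargs["theta_ec50_ranibizumab"] = init.theta_ec50_ranibizumab
    return PopulationParameters(**kwargs)


@dataclass
class FitResult:
    """Outcome of one population fit."""

    theta_hat: PopulationParameters
    eta_hat: pd.DataFrame  # per-patient conditional modes, index = patient ID
    ofv: float
    converged: bool
    n_function_evals: int
    start_point: dict[str, float]
    free_names: tuple[str, ...]
    drug_name: str
    ofv_history: list[float] = field(default_factory=list)

    def theta_vector(self) -> np.ndarray:
        """Free-parameter estimates in the order of ``free_names`` (log scale
        for thetas/omegas/sigma as optimised)."""
        return np.array([self.param_value(n) for n in self.free_names])

    def param_value(self, name: str) -> float:
        pop = self.theta_hat
        if name.startswith("omega_"):
            return math.log(max(pop.omega[name[6:]], _OMEGA_FLOOR))
        if name == "sigma":
            return math.log(pop.sigma)
        if name == "ec50":
            return pop.theta("ec50_aflibercept") if self.drug_name != "ranibizumab" else pop.theta("ec50_ranibizumab")
        return pop.theta(name)

    def to_json(self, path) -> None:
        payload = {
            "ofv": self.ofv,
            "converged": self.converged,
            "n_function_evals": self.n_function_evals,
            "drug": self.drug_name,
            "free_names": list(self.free_names),
            "estimates": {n: self.param_value(n) for n in self.free_names},
            "start_point": self.start_point,
            "inner_tol": INNER_TOL,
            "outer_gtol": OUTER_GTOL,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _check_single_drug(dataset: ObservationDataset, drug: DrugSpec) -> None:
    drugs = set(dataset.df["DRUG"].dropna().unique())
    if len(drugs) > 1:
        raise ValueError(f"fit_population expects a single-drug dataset, got {sorted(drugs)}")


def fit_population(
    dataset: ObservationDataset,
    drug: DrugSpec,
    init: PopulationParameters,
    fixed: frozenset[str] | set[str] = frozenset(),
    max_outer_iter: int = 300,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
    eta_warm: np.ndarray | None = None,
    gtol: float = OUTER_GTOL,
) -> FitResult:
    """Maximise the approximate marginal likelihood over (theta, Omega, sigma).

    ``fixed`` holds parameter names (see ``PARAM_NAMES``) frozen at their
    ``init`` values.  A random effect whose ``init`` variance is zero is
    removed from the model entirely.  Returns the best point found with
    ``converged=False`` if the optimizer does not converge.
    """
    if dataset.df.empty:
        raise ValueError("dataset is empty")
    _check_single_drug(dataset, drug)
    unknown = set(fixed) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names in fixed: {sorted(unknown)}")

    packed = _pack(dataset)
    n_pat = len(packed.ids)
    lp0 = _pop_to_lp(init, drug)
    omega0 = init.omega_vector()
    active = omega0 > _OMEGA_FLOOR
    sigma0 = init.sigma

    free_theta = [n for n in _LP_NAMES if n not in fixed]
    free_omega = [
        f"omega_{k}" for i, k in enumerate(RANDOM_EFFECTS) if active[i] and f"omega_{k}" not in fixed
    ]
    free_sigma = [] if "sigma" in fixed else ["sigma"]
    free_names = tuple(free_theta + free_omega + free_sigma)

    theta_idx = {n: i for i, n in enumerate(_LP_NAMES)}
    omega_idx = {f"omega_{k}": i for i, k in enumerate(RANDOM_EFFECTS)}

    def unpack(x: np.ndarray):
        lp = lp0.copy()
        om = omega0.copy()
        sig = sigma0
        for v, name in zip(x, free_names):
            if name in theta_idx:
                lp[theta_idx[name]] = v
            elif name in omega_idx:
                om[omega_idx[name]] = math.exp(v)
            else:
                sig = math.exp(v)
        return lp, om, sig

    x0 = []
    bounds = []
    for name in free_names:
        if name in theta_idx:
            v = lp0[theta_idx[name]]
            x0.append(v)
            bounds.append((v - _THETA_HALF_WIDTH, v + _THETA_HALF_WIDTH))
        elif name in omega_idx:
            x0.append(math.log(max(omega0[omega_idx[name]], _OMEGA_FLOOR)))
            bounds.append(_LOG_OMEGA_BOUNDS)
        else:
            x0.append(math.log(sigma0))
            bounds.append(_LOG_SIGMA_BOUNDS)
    x0 = np.array(x0)

    # Conditional-mode reference: every objective evaluation restarts the
    # inner search from the same per-patient modes, which makes the
    # approximate marginal likelihood a deterministic function of the
    # parameters (no dependence on the evaluation history).  The reference
    # is refreshed only between optimizer restarts.
    eta_ref = np.zeros((n_pat, 5)) if eta_warm is None else eta_warm.copy()
    eta_work = eta_ref.copy()
    n_evals = [0]
    free_lp_idx = np.array([theta_idx[n] for n in free_theta], dtype=np.int64)
    free_om_idx = np.array([omega_idx[n] for n in free_omega], dtype=np.int64)
    sigma_free = bool(free_sigma)
    grad_buf = np.zeros(len(free_names))
    last_fun = [np.inf]

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        lp, om, sig = unpack(x)
        n_evals[0] += 1
        eta_work[:] = eta_ref
        val = _kernels.population_fit_eval(
            lp,
            np.maximum(om, _OMEGA_FLOOR),
            active,
            sig,
            drug.k_el,
            packed.obs_y,
            packed.obs_t,
            packed.obs_off,
            packed.dose_t,
            packed.dose_a,
            packed.dose_off,
            eta_work,
            rtol,
            atol,
            INNER_TOL,
            300,
            free_lp_idx,
            free_om_idx,
            sigma_free,
            grad_buf,
        )
        if not np.isfinite(val):
            last_fun[0] = 1.0e12
            return 1.0e12, np.zeros_like(grad_buf)
        # normalized per patient so that stopping rules are invariant to
        # dataset duplication and cohort size
        last_fun[0] = float(val)
        return float(val) / n_pat, grad_buf / n_pat

    history: list[float] = []

    def callback(xk: np.ndarray) -> None:
        history.append(last_fun[0])
        # adopt the modes of the accepted iterate as the new reference: the
        # objective stays deterministic within each line search while inner
        # solves always start close to their solution
        eta_ref[:] = eta_work

    pos = {name: i for i, name in enumerate(free_names)}
    bounds_arr = np.array(bounds) if free_names else np.empty((0, 2))

    def em_sweeps(x: np.ndarray, max_sweeps: int = 40) -> tuple[np.ndarray, bool]:
        """Closed-form EM updates of the statistically flat directions.

        Conditional on the mode summaries, the maximising updates are exact:
        the population location of every random effect shifts by the mean
        conditional mode, each variance becomes the mean of (mode^2 +
        conditional variance), and sigma^2 absorbs the residual sum of
        squares plus its curvature correction.  These directions change the
        objective by less than the optimizer's noise floor, so quasi-Newton
        steps cannot resolve them; EM does, deterministically.
        """
        x = x.copy()
        sum_eta = np.zeros(5)
        sum_e2h = np.zeros(5)
        misc = np.zeros(4)
        for _ in range(max_sweeps):
            lp, om, sig = unpack(x)
            eta_work[:] = eta_ref
            n_ok = _kernels.population_em_stats(
                lp, np.maximum(om, _OMEGA_FLOOR), active, sig, drug.k_el,
                packed.obs_y, packed.obs_t, packed.obs_off,
                packed.dose_t, packed.dose_a, packed.dose_off,
                eta_work, rtol, atol, INNER_TOL, 300, sum_eta, sum_e2h, misc,
            )
            if n_ok == 0:
                return x, False
            eta_ref[:] = eta_work
            mean_eta = sum_eta / n_ok
            step = 0.0
            shift = np.zeros(5)
            for k, eff in enumerate(RANDOM_EFFECTS):
                if not active[k]:
                    continue
                if eff in pos:
                    i = pos[eff]
                    new = np.clip(x[i] + mean_eta[k], bounds_arr[i, 0], bounds_arr[i, 1])
                    shift[k] = new - x[i]
                    step = max(step, abs(shift[k]))
                    x[i] = new
                name = f"omega_{eff}"
                if name in pos:
                    i = pos[name]
                    e2 = sum_e2h[k] / n_ok - 2 * shift[k] * mean_eta[k] + shift[k] ** 2
                    new = np.clip(np.log(max(e2, 1.0e-12)), bounds_arr[i, 0], bounds_arr[i, 1])
                    step = max(step, abs(new - x[i]))
                    x[i] = new
            if "sigma" in pos:
                i = pos["sigma"]
                sig2_new = (misc[0] + sig * sig * misc[1]) / misc[2]
                new = np.clip(0.5 * np.log(max(sig2_new, 1.0e-12)),
                              bounds_arr[i, 0], bounds_arr[i, 1])
                step = max(step, abs(new - x[i]))
                x[i] = new
            eta_ref[:] = eta_ref - shift[None, :]
            if step < 1.0e-5:
                break
        return x, True

    # settle the reference modes at the starting point
    objective(x0)
    eta_ref[:] = eta_work

    if not free_names:
        res_x, res_fun, success = x0, objective(x0)[0], True
    else:
        best_f = np.inf
        best_x = x0
        best_eta = eta_ref.copy()
        last_status = 0
        x_start = x0
        prev_fun = np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _attempt in range(4):
                res = optimize.minimize(
                    objective,
                    x_start,
                    method="L-BFGS-B",
                    jac=True,
                    bounds=bounds,
                    callback=callback,
                    options={
                        "maxiter": max_outer_iter,
                        "ftol": 1.0e-13,
                        "gtol": gtol,
                    },
                )
                last_status = int(res.status)
                x_next = res.x
                f_next = float(res.fun)
                # EM phase for the flat directions, guarded by the objective
                x_em, em_ok = em_sweeps(res.x)
                if em_ok:
                    f_em, _ = objective(x_em)
                    if f_em <= f_next + 0.05:
                        x_next, f_next = x_em, float(f_em)
                        history.append(last_fun[0])
                if f_next < best_f:
                    best_f = f_next
                    best_x = x_next
                    objective(x_next)
                    best_eta = eta_work.copy()
                if res.status == 1:
                    break  # iteration budget exhausted
                # always give the search a second round (fresh quasi-Newton
                # state, refreshed mode reference); keep going while rounds
                # make real progress
                if _attempt >= 1 and prev_fun - f_next < 1.0e-5 * (1.0 + abs(f_next)):
                    break
                prev_fun = f_next
                x_start = x_next
                objective(x_start)
                eta_ref[:] = eta_work
        eta_ref[:] = best_eta
        success = last_status != 1 and np.isfinite(best_f)
        res_x, res_fun = best_x, best_f

    lp_hat, om_hat, sig_hat = unpack(res_x)
    at_floor = [
        k for i, k in enumerate(RANDOM_EFFECTS) if active[i] and om_hat[i] <= 2.0e-6
    ]
    if at_floor:
        warnings.warn(f"random-effect variance(s) at lower floor: {at_floor}", RuntimeWarning)
    # final inner pass so eta_hat corresponds to the returned estimates
    eta_work[:] = eta_ref
    final_ofv = _kernels.population_ofv(
        lp_hat,
        np.maximum(om_hat, _OMEGA_FLOOR),
        active,
        sig_hat,
        drug.k_el,
        packed.obs_y,
        packed.obs_t,
        packed.obs_off,
        packed.dose_t,
        packed.dose_a,
        packed.dose_off,
        eta_work,
        rtol,
        atol,
        INNER_TOL,
        300,
    )
    pop_hat = _lp_to_pop(lp_hat, om_hat, sig_hat, init, drug)
    return FitResult(
        theta_hat=pop_hat,
        eta_hat=pd.DataFrame(eta_work, index=packed.ids, columns=list(RANDOM_EFFECTS)),
        ofv=float(final_ofv),
        converged=success and np.isfinite(final_ofv),
        n_function_evals=n_evals[0],
        start_point=dict(zip(free_names, (float(v) for v in x0))),
        free_names=free_names,
        drug_name=drug.name,
        ofv_history=history,
    )


@dataclass
class WaterfallResult:
    """Multistart outcome: fits sorted by OFV plus plateau segmentation."""

    results: list[FitResult]  # ascending OFV
    ofvs: np.ndarray
    plateaus: list[list[int]]  # indices into ``results`` per plateau


def multistart(
    dataset: ObservationDataset,
    drug: DrugSpec,
    init: PopulationParameters,
    n_starts: int,
    dispersion: float = 0.5,
    seed: int | None = None,
    fixed: frozenset[str] | set[str] = frozenset(),
    **fit_kwargs,
) -> WaterfallResult:
    """Refit from randomized starts (log-scale Gaussian perturbations of the
    structural parameters) and order the resulting OFVs ascending.

    A gap of more than one OFV unit between consecutive sorted values starts
    a new plateau, flagging a potential distinct local optimum.
    """
    if n_starts < 2:
        raise ValueError("n_starts must be at least 2")
    rng = np.random.default_rng(seed)
    results = []
    failures = []
    for s in range(n_starts):
        start = init
        if s > 0:  # first start is the nominal init
            updates = {}
            for name in _LP_NAMES:
                if name in fixed:
                    continue
                if name == "ec50":
                    attr = (
                        "theta_ec50_ranibizumab"
                        if drug.name == "ranibizumab"
                        else "theta_ec50_aflibercept"
                    )
                else:
                    attr = f"theta_{name}"
                updates[attr] = getattr(init, attr) + rng.normal(0.0, dispersion)
            start = init.with_updates(**updates)
        try:
            results.append(fit_population(dataset, drug, start, fixed=fixed, **fit_kwargs))
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
            failures.append(f"start {s}: {exc}")
    if not results:
        raise RuntimeError("all multistart fits failed: " + "; ".join(failures))
    results.sort(key=lambda r: r.ofv)
    ofvs = np.array([r.ofv for r in results])
    return WaterfallResult(results=results, ofvs=ofvs, plateaus=segment_plateaus(ofvs))


def segment_plateaus(sorted_ofvs: np.ndarray, gap: float = 1.0) -> list[list[int]]:
    """Split ascending OFVs into plateaus wherever consecutive values differ
    by strictly more than ``gap`` (one unit by convention)."""
    plateaus: list[list[int]] = [[0]]
    for i in range(1, len(sorted_ofvs)):
        if sorted_ofvs[i] - sorted_ofvs[i - 1] > gap:
            plateaus.append([i])
        else:
            plateaus[-1].append(i)
    return plateaus


@dataclass
class LikelihoodProfile:
    """Profile likelihood of one parameter."""

    parameter: str
    grid: np.ndarray
    ofvs: np.ndarray
    smoothed_grid: np.ndarray
    smoothed_ofv: np.ndarray
    level: float
    ci: tuple[float, float]  # NaN side = open (not bracketed by the grid)
    estimate: float
    min_ofv: float

    @property
    def finite(self) -> bool:
        return bool(np.isfinite(self.ci[0]) and np.isfinite(self.ci[1]))


def loess_quadratic(
    x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float = 0.75
) -> np.ndarray:
    """Locally estimated scatterplot smoothing with tricube weights and a
    local quadratic polynomial."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    k = max(3, int(math.ceil(span * n)))
    out = np.empty(x_eval.size)
    for i, xe in enumerate(np.asarray(x_eval, float)):
        d = np.abs(x - xe)
        idx = np.argsort(d)[:k]
        dmax = d[idx].max()
        w = (1.0 - (d[idx] / (dmax if dmax > 0 else 1.0)) ** 3) ** 3
        w = np.clip(w, 1.0e-9, None)
        deg = 2 if idx.size >= 4 else 1
        coeffs = np.polyfit(x[idx] - xe, y[idx], deg, w=np.sqrt(w))
        out[i] = coeffs[-1]
    return out


def profile_likelihood(
    dataset: ObservationDataset,
    drug: DrugSpec,
    fit: FitResult,
    parameter: str,
    grid: np.ndarray,
    level: float = 0.95,
    fixed: frozenset[str] | set[str] = frozenset(),
    span: float = 0.75,
    **fit_kwargs,
) -> LikelihoodProfile:
    """Fix ``parameter`` at each grid value, reoptimize the rest, smooth the
    OFV curve and read the likelihood-ratio confidence interval.

    The CI is the set where the smoothed profile lies below
    ``min + chi2_1(level)`` (3.84 at 95%); a side the grid does not bracket
    is reported as NaN (open).
    """
    if not fit.converged:
        raise ValueError("profile requires a converged fit")
    if parameter not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {parameter}")
    grid = np.asarray(grid, float)
    estimate = fit.param_value(parameter)
    if not (grid.min() <= estimate <= grid.max()):
        raise ValueError("grid must bracket the estimate")

    base = fit.theta_hat
    ofvs = np.empty(grid.size)
    order = np.argsort(np.abs(grid - estimate))  # fit outward from the estimate
    results: dict[int, float] = {}
    for gi in order:
        value = grid[gi]
        start = base
        if parameter.startswith("omega_"):
            om = dict(base.omega)
            om[parameter[6:]] = math.exp(value)
            start = base.with_updates(omega=om)
        elif parameter == "sigma":
            start = base.with_updates(sigma=math.exp(value))
        elif parameter == "ec50":
            attr = (
                "theta_ec50_ranibizumab"
                if drug.name == "ranibizumab"
                else "theta_ec50_aflibercept"
            )
            start = base.with_updates(**{attr: value})
        else:
            start = base.with_updates(**{f"theta_{parameter}": value})
        refit = fit_population(
            dataset, drug, start, fixed=frozenset(fixed) | {parameter}, **fit_kwargs
        )
        results[gi] = refit.ofv
    for gi in range(grid.size):
        ofvs[gi] = results[gi]

    fine = np.linspace(grid.min(), grid.max(), 201)
    smooth = loess_quadratic(grid, ofvs, fine, span=span)
    min_ofv = float(min(smooth.min(), fit.ofv))
    threshold = min_ofv + stats.chi2.ppf(level, 1)
    below = smooth <= threshold
    if not below.any():
        ci = (float("nan"), float("nan"))
    else:
        lo_i, hi_i = np.nonzero(below)[0][[0, -1]]
        lo = fine[lo_i] if lo_i > 0 else float("nan")
        hi = fine[hi_i] if hi_i < fine.size - 1 else float("nan")
        ci = (float(lo), float(hi))
    return LikelihoodProfile(
        parameter=parameter,
        grid=grid,
        ofvs=ofvs,
        smoothed_grid=fine,
        smoothed_ofv=smooth,
        level=level,
        ci=ci,
        estimate=estimate,
        min_ofv=min_ofv,
    )


def predictions(
    dataset: ObservationDataset,
    drug: DrugSpec,
    pop: PopulationParameters,
    eta_hat: pd.DataFrame | None = None,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> pd.DataFrame:
    """Typical (PRED) and, when conditional modes are given, individual
    (IPRED) predictions for every observation record."""
    packed = _pack(dataset)
    lp_typ = _pop_to_lp(pop, drug)
    rows = []
    for p, pid in enumerate(packed.ids):
        sl = slice(packed.obs_off[p], packed.obs_off[p + 1])
        dsl = slice(packed.dose_off[p], packed.dose_off[p + 1])
        t = packed.obs_t[sl]
        pred = _kernels._predict(
            lp_typ, drug.k_el, packed.dose_t[dsl], packed.dose_a[dsl], t, rtol, atol
        )
        ipred = pred
        if eta_hat is not None:
            lp = lp_typ.copy()
            for k, name in enumerate(RANDOM_EFFECTS):
                lp[_kernels.ETA_TO_LP[k]] += float(eta_hat.loc[pid, name])
            ipred = _kernels._predict(
                lp, drug.k_el, packed.dose_t[dsl], packed.dose_a[dsl], t, rtol, atol
            )
        for j in range(t.size):
            rows.append((pid, t[j], packed.obs_y[sl][j], pred[j], ipred[j]))
    return pd.DataFrame(rows, columns=["ID", "TIME", "DV", "PRED", "IPRED"])
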