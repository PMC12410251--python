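"""Structural PK/PD model: analytic PK, CST dynamics, trajectory simulation.

Drug amount in the vitreous follows first-order elimination with bolus IVT
doses, so PK(t) is an exact superposition of decaying exponentials and is
never integrated numerically.  CST follows an indirect-response model in
which the drug stimulates the first-order loss rate through a Hill (Emax)
term; the scalar CST ODE is integrated with an adaptive Dormand-Prince 5(4)
scheme (default rtol/atol 1e-8), restarted at each dose event.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from ._kernels import EPS_PK
from .params import DoseEvent, DrugSpec, IndividualParameters

__all__ = ["pk_amount", "cst_derivative", "simulate_trajectory", "EPS_PK"]

#: Default integrator tolerances (relative, absolute in µm).
RTOL = 1.0e-8
ATOL = 1.0e-8


def _dose_arrays(doses: list[DoseEvent]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([d.time for d in doses], dtype=float)
    amounts = np.array([d.amount for d in doses], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("doses must be sorted by time")
    return times, amounts


def pk_amount(
    individual: IndividualParameters,
    drug: DrugSpec,
    doses: list[DoseEvent],
    t: float | np.ndarray,
) -> float | np.ndarray:
    """Vitreous drug amount (mg) at time ``t`` (days).

    Exact solution of first-order elimination with bolus inputs:
    ``PK(t) = pk0 e^{-kel t} + sum_{time<=t} amount e^{-kel (t - time)}``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    dose_t, dose_a = _dose_arrays(doses)
    out = _kernels.pk_superposition(t_arr, individual.pk0, drug.k_el, dose_t, dose_a)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def cst_derivative(cst: float, pk: float, individual: IndividualParameters) -> float:
    """dCST/dt (µm/day): synthesis at ``kin`` minus stimulated first-order loss.

    The drug effect multiplies the loss rate by
    ``1 + emax (pk+eps)^h / (ec50^h + (pk+eps)^h)`` with ``eps = 1e-8``.
    """
    if cst <= 0:
        raise ValueError("cst must be positive")
    if pk < 0:
        raise ValueError("pk must be non-negative")
    return float(
        _kernels.cst_rhs(
            cst,
            pk,
            individual.kin,
            individual.kout,
            individual.emax,
            individual.ec50,
            individual.h,
        )
    )


def simulate_trajectory(
    individual: IndividualParameters,
    drug: DrugSpec,
    doses: list[DoseEvent],
    times: np.ndarray | list[float],
    rtol: float = RTOL,
    atol: float = ATOL,
) -> np.ndarray:
    """Noise-free CST (µm) at the requested days, starting from ``cst0`` at day 0.

    ``times`` must be sorted and non-negative.  Raises ``RuntimeError`` naming
    the parameter set if the integrator fails.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) < 0) or t[0] < 0:
        raise ValueError("times must be sorted and non-negative")
    dose_t, dose_a = _dose_arrays(doses)
    out = _kernels.simulate_cst(
        individual.cst_del,
        individual.kin,
        individual.ec50,
        individual.cst_min,
        individual.cst0,
        individual.pk0,
        individual.h,
        drug.k_el,
        dose_t,
        dose_a,
        t,
        rtol,
        atol,
    )
    if np.any(np.isnan(out)):
        raise RuntimeError(f"CST integration failed for parameters {individual}")
    return out
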