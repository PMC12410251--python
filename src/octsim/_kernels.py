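"""Numba kernels: CST trajectory integration and Laplace marginal likelihood.

The PK is a superposition of decaying boluses and is evaluated analytically
inside the CST right-hand side; only the scalar CST ODE is integrated, with an
adaptive Dormand-Prince 5(4) scheme restarted at every dose event so the PK
jump never falls inside a solver step.

The population objective is -2 log of a Laplace approximation to the marginal
likelihood: per patient, the random-effect vector is optimised to its
conditional mode by a Levenberg-Marquardt iteration on the penalised residual
system, and the curvature term uses the Gauss-Newton Hessian
``J'J/sigma^2 + Omega^{-1}`` (first-order conditional flavour).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Numerical offset added to PK inside the Hill term (kept verbatim from the
#: model definition; irrelevant at therapeutic amounts).
EPS_PK = 1.0e-8

#: Map from random-effect index (canonical order cst_del, ec50, cst_min,
#: cst0, pk0) to the index in the 7-vector of individual log parameters
#: (cst_del, kin, ec50, cst_min, cst0, pk0, h).
ETA_TO_LP = np.array([0, 2, 3, 4, 5], dtype=np.int64)


@njit(cache=True)
def pk_superposition(t, pk0, kel, dose_t, dose_a):
    """Analytic vitreous drug amount at times ``t`` (mg).

    ``PK(t) = pk0 e^{-kel t} + sum_{doses, time<=t} amount e^{-kel (t-time)}``.
    """
    out = np.empty(t.shape[0])
    for i in range(t.shape[0]):
        a = pk0 * np.exp(-kel * t[i])
        for j in range(dose_t.shape[0]):
            if dose_t[j] <= t[i]:
                a += dose_a[j] * np.exp(-kel * (t[i] - dose_t[j]))
        out[i] = a
    return out


@njit(cache=True)
def cst_rhs(cst, pk, kin, kout, emax, ec50, h):
    """Right-hand side of the indirect-response CST ODE (µm/day).

    The Hill fraction is evaluated as 1 / (1 + (ec50/(pk+eps))^h), which is
    algebraically identical to (pk+eps)^h / (ec50^h + (pk+eps)^h) but cannot
    underflow to 0/0 for extreme Hill exponents."""
    pe = pk + EPS_PK
    return kin - kout * (1.0 + emax / (1.0 + (ec50 / pe) ** h)) * cst


# Dormand-Prince 5(4) tableau
_C2, _C3, _C4, _C5 = 0.2, 0.3, 0.8, 8.0 / 9.0
_A21 = 0.2
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
_E1, _E3, _E4, _E5, _E6, _E7 = (
    35.0 / 384.0 - 5179.0 / 57600.0,
    500.0 / 1113.0 - 7571.0 / 16695.0,
    125.0 / 192.0 - 393.0 / 640.0,
    -2187.0 / 6784.0 + 92097.0 / 339200.0,
    11.0 / 84.0 - 187.0 / 2100.0,
    -1.0 / 40.0,
)


@njit(cache=True)
def _advance(t, y, t_stop, dt, pk_seg, t_seg, kel, kin, kout, emax, ec50, h, rtol, atol):
    """Integrate the scalar CST ODE from ``t`` to ``t_stop`` (no dose inside).

    Returns (y, dt) with dt the error-controlled proposal for the next step.
    """
    nsteps = 0
    while t < t_stop - 1.0e-10:
        if dt < 1.0e-12:
            dt = 1.0e-12
        hstep = dt
        clamped = False
        if hstep > t_stop - t:
            hstep = t_stop - t
            clamped = True

        p1 = pk_seg * np.exp(-kel * (t - t_seg))
        k1 = cst_rhs(y, p1, kin, kout, emax, ec50, h)
        p2 = pk_seg * np.exp(-kel * (t + _C2 * hstep - t_seg))
        k2 = cst_rhs(y + hstep * _A21 * k1, p2, kin, kout, emax, ec50, h)
        p3 = pk_seg * np.exp(-kel * (t + _C3 * hstep - t_seg))
        k3 = cst_rhs(y + hstep * (_A31 * k1 + _A32 * k2), p3, kin, kout, emax, ec50, h)
        p4 = pk_seg * np.exp(-kel * (t + _C4 * hstep - t_seg))
        k4 = cst_rhs(y + hstep * (_A41 * k1 + _A42 * k2 + _A43 * k3), p4, kin, kout, emax, ec50, h)
        p5 = pk_seg * np.exp(-kel * (t + _C5 * hstep - t_seg))
        k5 = cst_rhs(
            y + hstep * (_A51 * k1 + _A52 * k2 + _A53 * k3 + _A54 * k4),
            p5,
            kin,
            kout,
            emax,
            ec50,
            h,
        )
        p6 = pk_seg * np.exp(-kel * (t + hstep - t_seg))
        k6 = cst_rhs(
            y + hstep * (_A61 * k1 + _A62 * k2 + _A63 * k3 + _A64 * k4 + _A65 * k5),
            p6,
            kin,
            kout,
            emax,
            ec50,
            h,
        )
        ynew = y + hstep * (_B1 * k1 + _B3 * k3 + _B4 * k4 + _B5 * k5 + _B6 * k6)
        k7 = cst_rhs(ynew, p6, kin, kout, emax, ec50, h)
        err = hstep * (_E1 * k1 + _E3 * k3 + _E4 * k4 + _E5 * k5 + _E6 * k6 + _E7 * k7)

        sc = atol + rtol * max(abs(y), abs(ynew))
        ratio = abs(err) / sc
        if ratio <= 1.0:
            t = t + hstep
            y = ynew
            if ratio < 1.0e-300:
                fac = 5.0
            else:
                fac = 0.9 * ratio ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
                elif fac < 0.2:
                    fac = 0.2
            if clamped:
                grown = hstep * fac
                if grown > dt:
                    dt = grown
            else:
                dt = hstep * fac
        else:
            fac = 0.9 * ratio ** (-0.25)
            if fac < 0.1:
                fac = 0.1
            dt = hstep * fac
        nsteps += 1
        if nsteps > 2_000_000:
            return np.nan, dt
    return y, dt


@njit(cache=True)
def simulate_cst(cst_del, kin, ec50, cst_min, cst0, pk0, h, kel, dose_t, dose_a, obs_t, rtol, atol):
    """Noise-free CST (µm) at sorted observation times for one patient.

    Doses and observations at the same instant apply the dose first.  Returns
    NaN-filled output if the integrator exceeds its step budget (signalling a
    pathological parameter set to the caller).
    """
    n_obs = obs_t.shape[0]
    out = np.empty(n_obs)
    kout = kin / (cst_min + cst_del)
    emax = cst_del / cst_min
    
    t = 0.0
    y = cst0
    pk_seg = pk0
    t_seg = 0.0
    i_dose = 0
    n_dose = dose_t.shape[0]
    while i_dose < n_dose and dose_t[i_dose] <= 0.0:
        pk_seg += dose_a[i_dose]
        i_dose += 1
    i_obs = 0
    while i_obs < n_obs and obs_t[i_obs] <= 0.0:
        out[i_obs] = y
        i_obs += 1

    dt = 0.25
    while i_obs < n_obs or i_dose < n_dose:
        t_next_obs = obs_t[i_obs] if i_obs < n_obs else 1.0e300
        t_next_dose = dose_t[i_dose] if i_dose < n_dose else 1.0e300
        t_stop = min(t_next_obs, t_next_dose)
        if t_stop > t:
            y, dt = _advance(
                t, y, t_stop, dt, pk_seg, t_seg, kel, kin, kout, emax, ec50, h, rtol, atol
            )
            if np.isnan(y):
                for k in range(i_obs, n_obs):
                    out[k] = np.nan
                return out
            t = t_stop
        while i_dose < n_dose and dose_t[i_dose] <= t_stop:
            pk_seg = pk_seg * np.exp(-kel * (t_stop - t_seg)) + dose_a[i_dose]
            t_seg = t_stop
            i_dose += 1
        while i_obs < n_obs and obs_t[i_obs] <= t_stop:
            out[i_obs] = y
            i_obs += 1
    return out


@njit(cache=True)
def _predict(lp, kel, dose_t, dose_a, obs_t, rtol, atol):
    """CST prediction from a 7-vector of individual log parameters."""
    return simulate_cst(
        np.exp(lp[0]),
        np.exp(lp[1]),
        np.exp(lp[2]),
        np.exp(lp[3]),
        np.exp(lp[4]),
        np.exp(lp[5]),
        np.exp(lp[6]),
        kel,
        dose_t,
        dose_a,
        obs_t,
        rtol,
        atol,
    )


@njit(cache=True)
def _chol_solve(A, b):
    """Solve A x = b for symmetric positive-definite A (tiny d) via Cholesky.

    Returns (x, logdet, ok)."""
    d = A.shape[0]
    L = np.zeros((d, d))
    logdet = 0.0
    for i in range(d):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return b * 0.0, 0.0, False
                L[i, i] = np.sqrt(s)
                logdet += 2.0 * np.log(L[i, i])
            else:
                L[i, j] = s / L[j, j]
    # forward/back substitution
    zv = np.empty(d)
    for i in range(d):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * zv[k]
        zv[i] = s / L[i, i]
    x = np.empty(d)
    for i in range(d - 1, -1, -1):
        s = zv[i]
        for k in range(i + 1, d):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x, logdet, True




@njit(cache=True)
def _eta_mode(
    y,
    obs_t,
    dose_t,
    dose_a,
    kel,
    lp_typ,
    omega,
    idx,
    sigma,
    eta,
    J,
    rtol,
    atol,
    inner_tol,
    max_iter,
):
    """Levenberg-Marquardt search for the conditional mode of the random
    effects of one patient.

    ``idx`` lists the active effect indices (length d); ``eta`` (5,) is warm
    started and overwritten; ``J`` (n, d) receives the finite-difference
    Jacobian of the prediction wrt the active effects, formed within
    ``10 * inner_tol`` of the returned mode.  Returns (f, rss, ok).
    """
    n = y.shape[0]
    d = idx.shape[0]
    sig2 = sigma * sigma

    lp = lp_typ.copy()
    for j in range(d):
        lp[ETA_TO_LP[idx[j]]] = lp_typ[ETA_TO_LP[idx[j]]] + eta[idx[j]]
    f = _predict(lp, kel, dose_t, dose_a, obs_t, rtol, atol)
    if np.isnan(f[0]) or np.isnan(f[n - 1]):
        return f, -1.0, 0

    rss = 0.0
    for i in range(n):
        rss += (y[i] - f[i]) ** 2
    g = rss / sig2
    for j in range(d):
        g += eta[idx[j]] ** 2 / omega[idx[j]]
    if d == 0:
        return f, rss, 1
    if rss / (sig2 * n) > 100.0:
        # a stale warm start can look catastrophic for this patient; judge
        # only after retrying from the prior mean
        nonzero = False
        for j in range(d):
            if eta[idx[j]] != 0.0:
                nonzero = True
        if nonzero:
            f0 = _predict(lp_typ, kel, dose_t, dose_a, obs_t, rtol, atol)
            if not np.isnan(f0[0]):
                rss0 = 0.0
                for i in range(n):
                    rss0 += (y[i] - f0[i]) ** 2
                if rss0 / sig2 < g:
                    for k in range(5):
                        eta[k] = 0.0
                    lp = lp_typ.copy()
                    f = f0
                    rss = rss0
                    g = rss0 / sig2
    if rss / (sig2 * n) > 1.0e5:
        # hopeless region of the outer search; skip mode refinement entirely
        return f, rss, 2

    lam = 1.0e-3
    step_eta = 1.0e-4
    JtJ = np.empty((d, d))
    rhs = np.empty(d)
    eta_at_J = eta.copy()
    stale = True
    for _ in range(max_iter):
        fresh = stale
        if stale:
            for j in range(d):
                lpj = lp.copy()
                lpj[ETA_TO_LP[idx[j]]] += step_eta
                fj = _predict(lpj, kel, dose_t, dose_a, obs_t, rtol, atol)
                for i in range(n):
                    J[i, j] = (fj[i] - f[i]) / step_eta
            for a in range(d):
                for b in range(a + 1):
                    s = 0.0
                    for i in range(n):
                        s += J[i, a] * J[i, b]
                    JtJ[a, b] = s / sig2
                    JtJ[b, a] = s / sig2
            eta_at_J = eta.copy()
            stale = False
        for a in range(d):
            s = 0.0
            for i in range(n):
                s += J[i, a] * (y[i] - f[i])
            rhs[a] = s / sig2 - eta[idx[a]] / omega[idx[a]]

        accepted = False
        converged = False
        max_step = 0.0
        for _inner in range(30):
            A = JtJ.copy()
            for a in range(d):
                A[a, a] += 1.0 / omega[idx[a]] + lam * (JtJ[a, a] + 1.0 / omega[idx[a]])
            delta, _, ok = _chol_solve(A, rhs)
            if not ok:
                lam *= 10.0
                continue
            max_step = 0.0
            for j in range(d):
                if abs(delta[j]) > max_step:
                    max_step = abs(delta[j])
            if lam <= 1.0e-2 and max_step < inner_tol:
                converged = True  # already at the (linearized) stationary point
                break
            eta_new = eta.copy()
            for j in range(d):
                eta_new[idx[j]] = eta[idx[j]] + delta[j]
            lp_new = lp_typ.copy()
            for j in range(d):
                lp_new[ETA_TO_LP[idx[j]]] = lp_typ[ETA_TO_LP[idx[j]]] + eta_new[idx[j]]
            f_new = _predict(lp_new, kel, dose_t, dose_a, obs_t, rtol, atol)
            if np.isnan(f_new[0]):
                lam *= 10.0
                continue
            rss_new = 0.0
            for i in range(n):
                rss_new += (y[i] - f_new[i]) ** 2
            g_new = rss_new / sig2
            for j in range(d):
                g_new += eta_new[idx[j]] ** 2 / omega[idx[j]]
            if g_new <= g + 1.0e-12:
                gdiff = g - g_new
                predicted = 0.0
                for j in range(d):
                    predicted += delta[j] * rhs[j]
                for k in range(5):
                    eta[k] = eta_new[k]
                lp = lp_new
                f = f_new
                rss = rss_new
                g = g_new
                lam = max(lam * 0.3, 1.0e-10)
                accepted = True
                moved = 0.0
                for k in range(5):
                    if abs(eta[k] - eta_at_J[k]) > moved:
                        moved = abs(eta[k] - eta_at_J[k])
                # coarse phase tolerates drift; the endgame needs a fresh
                # linearization so the fixed point is hit exactly
                if moved > 0.05 or (max_step < 0.01 and moved > 0.002):
                    stale = True
                if max_step < inner_tol:
                    converged = True
                elif gdiff < 1.0e-12 * (1.0 + abs(g)) and predicted < 1.0e-10:
                    converged = True  # objective flat to numerical precision
                break
            else:
                lam *= 10.0
                if lam > 1.0e10:
                    break
        if converged:
            moved = 0.0
            for k in range(5):
                if abs(eta[k] - eta_at_J[k]) > moved:
                    moved = abs(eta[k] - eta_at_J[k])
            if fresh or moved <= 10.0 * inner_tol:
                break
            stale = True  # verify convergence against a fresh linearization
        elif not accepted:
            if fresh:
                break  # stuck even with a fresh Jacobian
            stale = True
            lam = 1.0e-3

    # make sure J corresponds to the final mode
    moved = 0.0
    for k in range(5):
        if abs(eta[k] - eta_at_J[k]) > moved:
            moved = abs(eta[k] - eta_at_J[k])
    if moved > 10.0 * inner_tol:
        for j in range(d):
            lpj = lp.copy()
            lpj[ETA_TO_LP[idx[j]]] += step_eta
            fj = _predict(lpj, kel, dose_t, dose_a, obs_t, rtol, atol)
            for i in range(n):
                J[i, j] = (fj[i] - f[i]) / step_eta
    return f, rss, 1


@njit(cache=True)
def patient_eval(
    y,
    obs_t,
    dose_t,
    dose_a,
    kel,
    lp_typ,
    omega,
    active,
    sigma,
    eta,
    rtol,
    atol,
    inner_tol,
    max_iter,
    want_grad,
    free_lp_idx,
    free_om_idx,
    sigma_free,
    grad_out,
):
    """Laplace -2 log-likelihood contribution of one patient, optionally with
    its gradient accumulated into ``grad_out``.

    The gradient treats the conditional modes as fixed (envelope
    approximation) and the structural parts reuse the mode Jacobian; the
    variance and residual-SD components are analytic through the curvature
    matrix.  Layout of ``grad_out``: free structural log-parameters (indices
    ``free_lp_idx`` into the 7-vector), then free log-variances (indices
    ``free_om_idx`` into the effect vector), then log-sigma if
    ``sigma_free``.
    """
    n = y.shape[0]
    d = 0
    for k in range(5):
        if active[k]:
            d += 1
    idx = np.empty(d, dtype=np.int64)
    j = 0
    for k in range(5):
        if active[k]:
            idx[j] = k
            j += 1
        else:
            eta[k] = 0.0

    J = np.empty((n, d))
    f, rss, status = _eta_mode(
        y, obs_t, dose_t, dose_a, kel, lp_typ, omega, idx, sigma, eta, J,
        rtol, atol, inner_tol, max_iter,
    )
    if status == 0:
        return np.inf

    sig2 = sigma * sigma
    two_pi = 2.0 * np.pi
    n_free_lp = free_lp_idx.shape[0]
    n_free_om = free_om_idx.shape[0]

    if status == 2 and d > 0:
        # far from any optimum: residual and prior terms only, no curvature
        ofv = n * np.log(two_pi * sig2) + rss / sig2
        for j in range(d):
            k = idx[j]
            ofv += np.log(omega[k]) + eta[k] ** 2 / omega[k]
        if want_grad:
            lp = lp_typ.copy()
            for j in range(d):
                lp[ETA_TO_LP[idx[j]]] = lp_typ[ETA_TO_LP[idx[j]]] + eta[idx[j]]
            for q in range(n_free_lp):
                lpj = lp.copy()
                lpj[free_lp_idx[q]] += 1.0e-4
                fj = _predict(lpj, kel, dose_t, dose_a, obs_t, rtol, atol)
                rssj = 0.0
                for i in range(n):
                    rssj += (y[i] - fj[i]) ** 2
                grad_out[q] += (rssj - rss) / (1.0e-4 * sig2)
            for q in range(n_free_om):
                for cc in range(d):
                    if idx[cc] == free_om_idx[q]:
                        k = idx[cc]
                        grad_out[n_free_lp + q] += 1.0 - eta[k] ** 2 / omega[k]
                        break
            if sigma_free:
                grad_out[n_free_lp + n_free_om] += 2.0 * n - 2.0 * rss / sig2
        return ofv

    if d == 0:
        ofv = n * np.log(two_pi * sig2) + rss / sig2
        if want_grad:
            lp = lp_typ.copy()
            for q in range(n_free_lp):
                lpj = lp.copy()
                lpj[free_lp_idx[q]] += 1.0e-4
                fj = _predict(lpj, kel, dose_t, dose_a, obs_t, rtol, atol)
                rssj = 0.0
                for i in range(n):
                    rssj += (y[i] - fj[i]) ** 2
                grad_out[q] += (rssj - rss) / (1.0e-4 * sig2)
            if sigma_free:
                grad_out[n_free_lp + n_free_om] += 2.0 * n - 2.0 * rss / sig2
        return ofv

    H = np.empty((d, d))
    for a in range(d):
        for b in range(a + 1):
            s = 0.0
            for i in range(n):
                s += J[i, a] * J[i, b]
            H[a, b] = s / sig2
            H[b, a] = s / sig2
        H[a, a] += 1.0 / omega[idx[a]]
    unit = np.zeros(d)
    unit[0] = 1.0
    _, logdet, ok2 = _chol_solve(H, unit)
    if not ok2:
        return np.inf

    ofv = n * np.log(two_pi * sig2) + rss / sig2 + logdet
    for j in range(d):
        k = idx[j]
        ofv += np.log(omega[k]) + eta[k] ** 2 / omega[k]

    if want_grad:
        # diagonal of H^{-1} for the analytic variance / sigma parts
        hinv_diag = np.empty(d)
        for c in range(d):
            e = np.zeros(d)
            e[c] = 1.0
            x, _, _ = _chol_solve(H, e)
            hinv_diag[c] = x[c]
        # individual log parameters at the mode
        lp = lp_typ.copy()
        for j in range(d):
            lp[ETA_TO_LP[idx[j]]] = lp_typ[ETA_TO_LP[idx[j]]] + eta[idx[j]]
        for q in range(n_free_lp):
            lpq = free_lp_idx[q]
            col = -1
            for c in range(d):
                if ETA_TO_LP[idx[c]] == lpq:
                    col = c
                    break
            if col >= 0:
                s = 0.0
                for i in range(n):
                    s += (y[i] - f[i]) * J[i, col]
                grad_out[q] += -2.0 * s / sig2
            else:
                lpj = lp.copy()
                lpj[lpq] += 1.0e-4
                fj = _predict(lpj, kel, dose_t, dose_a, obs_t, rtol, atol)
                rssj = 0.0
                for i in range(n):
                    rssj += (y[i] - fj[i]) ** 2
                grad_out[q] += (rssj - rss) / (1.0e-4 * sig2)
        for q in range(n_free_om):
            c = -1
            for cc in range(d):
                if idx[cc] == free_om_idx[q]:
                    c = cc
                    break
            if c >= 0:
                k = idx[c]
                grad_out[n_free_lp + q] += (
                    1.0 - eta[k] ** 2 / omega[k] - hinv_diag[c] / omega[k]
                )
        if sigma_free:
            s = 0.0
            for c in range(d):
                s += hinv_diag[c] / omega[idx[c]]
            grad_out[n_free_lp + n_free_om] += (
                2.0 * n - 2.0 * rss / sig2 - 2.0 * d + 2.0 * s
            )
    return ofv


@njit(cache=True)
def patient_laplace(
    y,
    obs_t,
    dose_t,
    dose_a,
    kel,
    lp_typ,
    omega,
    active,
    sigma,
    eta,
    rtol,
    atol,
    inner_tol,
    max_iter,
):
    """Laplace -2 log-likelihood for one patient (no gradient)."""
    dummy_i = np.empty(0, dtype=np.int64)
    dummy_g = np.empty(0)
    return patient_eval(
        y, obs_t, dose_t, dose_a, kel, lp_typ, omega, active, sigma, eta,
        rtol, atol, inner_tol, max_iter, False, dummy_i, dummy_i, False, dummy_g,
    )


@njit(cache=True)
def population_ofv(
    theta_lp,
    omega,
    active,
    sigma,
    kel,
    obs_y,
    obs_t,
    obs_off,
    dose_t,
    dose_a,
    dose_off,
    eta_warm,
    rtol,
    atol,
    inner_tol,
    max_iter,
):
    """Total -2 log Laplace marginal likelihood over all patients.

    Flat event arrays with per-patient offset vectors; ``eta_warm``
    (n_pat, 5) holds warm-started conditional modes, updated in place.
    """
    dummy_i = np.empty(0, dtype=np.int64)
    dummy_g = np.empty(0)
    n_pat = obs_off.shape[0] - 1
    total = 0.0
    for p in range(n_pat):
        total += patient_eval(
            obs_y[obs_off[p] : obs_off[p + 1]],
            obs_t[obs_off[p] : obs_off[p + 1]],
            dose_t[dose_off[p] : dose_off[p + 1]],
            dose_a[dose_off[p] : dose_off[p + 1]],
            kel,
            theta_lp,
            omega,
            active,
            sigma,
            eta_warm[p],
            rtol,
            atol,
            inner_tol,
            max_iter,
            False,
            dummy_i,
            dummy_i,
            False,
            dummy_g,
        )
        if not np.isfinite(total):
            return np.inf
    return total


@njit(cache=True)
def population_fit_eval(
    theta_lp,
    omega,
    active,
    sigma,
    kel,
    obs_y,
    obs_t,
    obs_off,
    dose_t,
    dose_a,
    dose_off,
    eta_warm,
    rtol,
    atol,
    inner_tol,
    max_iter,
    free_lp_idx,
    free_om_idx,
    sigma_free,
    grad_out,
):
    """Population OFV together with its (envelope) gradient in ``grad_out``."""
    for q in range(grad_out.shape[0]):
        grad_out[q] = 0.0
    n_pat = obs_off.shape[0] - 1
    total = 0.0
    for p in range(n_pat):
        total += patient_eval(
            obs_y[obs_off[p] : obs_off[p + 1]],
            obs_t[obs_off[p] : obs_off[p + 1]],
            dose_t[dose_off[p] : dose_off[p + 1]],
            dose_a[dose_off[p] : dose_off[p + 1]],
            kel,
            theta_lp,
            omega,
            active,
            sigma,
            eta_warm[p],
            rtol,
            atol,
            inner_tol,
            max_iter,
            True,
            free_lp_idx,
            free_om_idx,
            sigma_free,
            grad_out,
        )
        if not np.isfinite(total):
            return np.inf
    return total


@njit(cache=True)
def mc_mean_endpoints(
    samples,
    kind,
    target,
    base_lp,
    base_logom,
    z,
    kel,
    dose_t,
    dose_a,
    t_end,
    rtol,
    atol,
):
    """Model-implied endpoint statistic for each sampled parameter vector.

    ``samples`` (S, p): log-scale parameter draws; entry j of a draw lands in
    the structural log-parameter vector when ``kind[j] == 0`` (at index
    ``target[j]``) or in the log-variance vector when ``kind[j] == 1``;
    other entries (e.g. log sigma) are ignored.  ``z`` (M, 5) holds shared
    standard-normal draws: the statistic is the mean endpoint CST over the M
    implied virtual patients (M = 0 returns the typical, eta = 0, endpoint).
    """
    S = samples.shape[0]
    M = z.shape[0]
    out = np.empty(S)
    obs = np.empty(1)
    obs[0] = t_end
    for s in range(S):
        lp0 = base_lp.copy()
        logom = base_logom.copy()
        for j in range(samples.shape[1]):
            if kind[j] == 0:
                lp0[target[j]] = samples[s, j]
            elif kind[j] == 1:
                logom[target[j]] = samples[s, j]
        if M == 0:
            v = _predict(lp0, kel, dose_t, dose_a, obs, rtol, atol)[0]
            out[s] = v
            continue
        acc = 0.0
        for m in range(M):
            lp = lp0.copy()
            for k in range(5):
                lp[ETA_TO_LP[k]] += np.sqrt(np.exp(logom[k])) * z[m, k]
            acc += _predict(lp, kel, dose_t, dose_a, obs, rtol, atol)[0]
        out[s] = acc / M
    return out


@njit(cache=True)
def population_em_stats(
    theta_lp,
    omega,
    active,
    sigma,
    kel,
    obs_y,
    obs_t,
    obs_off,
    dose_t,
    dose_a,
    dose_off,
    eta_warm,
    rtol,
    atol,
    inner_tol,
    max_iter,
    sum_eta,
    sum_e2h,
    misc,
):
    """Conditional-mode summaries for EM updates of the flat directions.

    Fills ``sum_eta[k]`` with the sum of conditional modes and ``sum_e2h[k]``
    with the sum of (mode^2 + conditional variance) per active effect, and
    ``misc = [rss_total, trace_term, n_obs_total, ofv]`` where ``trace_term``
    accumulates d_i - tr(H_i^{-1} Omega^{-1}) (the residual-variance
    correction).  Returns the number of patients summarised (0 on failure).
    """
    n_pat = obs_off.shape[0] - 1
    for k in range(5):
        sum_eta[k] = 0.0
        sum_e2h[k] = 0.0
    misc[0] = 0.0
    misc[1] = 0.0
    misc[2] = 0.0
    misc[3] = 0.0
    d = 0
    for k in range(5):
        if active[k]:
            d += 1
    idx = np.empty(d, dtype=np.int64)
    j = 0
    for k in range(5):
        if active[k]:
            idx[j] = k
            j += 1
    sig2 = sigma * sigma
    two_pi = 2.0 * np.pi
    for p in range(n_pat):
        y = obs_y[obs_off[p] : obs_off[p + 1]]
        t = obs_t[obs_off[p] : obs_off[p + 1]]
        dt_ = dose_t[dose_off[p] : dose_off[p + 1]]
        da = dose_a[dose_off[p] : dose_off[p + 1]]
        n = y.shape[0]
        eta = eta_warm[p]
        for k in range(5):
            if not active[k]:
                eta[k] = 0.0
        J = np.empty((n, d))
        f, rss, status = _eta_mode(
            y, t, dt_, da, kel, theta_lp, omega, idx, sigma, eta, J,
            rtol, atol, inner_tol, max_iter,
        )
        if status != 1:
            return 0
        H = np.empty((d, d))
        for a in range(d):
            for b in range(a + 1):
                s = 0.0
                for i in range(n):
                    s += J[i, a] * J[i, b]
                H[a, b] = s / sig2
                H[b, a] = s / sig2
            H[a, a] += 1.0 / omega[idx[a]]
        unit = np.zeros(d)
        if d > 0:
            unit[0] = 1.0
        x_, logdet, ok = _chol_solve(H, unit) if d > 0 else (unit, 0.0, True)
        if not ok:
            return 0
        trace_term = 0.0
        for c in range(d):
            e = np.zeros(d)
            e[c] = 1.0
            xs, _, _ = _chol_solve(H, e)
            hinv_cc = xs[c]
            k = idx[c]
            sum_eta[k] += eta[k]
            sum_e2h[k] += eta[k] * eta[k] + hinv_cc
            trace_term += 1.0 - hinv_cc / omega[k]
        misc[0] += rss
        misc[1] += trace_term
        misc[2] += n
        ofv = n * np.log(two_pi * sig2) + rss / sig2 + logdet
        for c in range(d):
            k = idx[c]
            ofv += np.log(omega[k]) + eta[k] * eta[k] / omega[k]
        misc[3] += ofv
    return n_pat
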