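"""Structural-model tests: analytic PK, CST dynamics, parameter algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import octsim
from octsim import DoseEvent, cst_derivative, derive_individual, pk_amount, simulate_trajectory


def scipy_reference(ind, drug, doses, obs, rtol=1e-10):
    """Independent stiff-capable integrator of the coupled PK/CST system with
    impulse dosing handled by segment restarts."""
    def rhs(t, y):
        cst, pk = y
        pe = pk + 1e-8
        ph = pe**ind.h
        dcst = ind.kin - ind.kout * (1 + ind.emax * ph / (ind.ec50**ind.h + ph)) * cst
        return [dcst, -drug.k_el * pk]

    obs = np.asarray(obs, float)
    dose_t = [d.time for d in doses]
    out = np.empty(obs.size)
    i_obs = int(np.sum(obs <= 0.0))
    out[:i_obs] = ind.cst0
    t, y = 0.0, [ind.cst0, ind.pk0]
    for knot in sorted(set(dose_t) | {obs.max()}):
        seg = [o for o in obs if t < o <= knot]
        sol = solve_ivp(rhs, (t, knot), y, method="LSODA", rtol=rtol, atol=rtol,
                        t_eval=sorted(set(seg) | {knot}))
        for o in seg:
            out[i_obs] = sol.y[0][list(sol.t).index(o)]
            i_obs += 1
        y = [sol.y[0][-1], sol.y[1][-1]]
        if knot in dose_t:
            y[1] += doses[dose_t.index(knot)].amount
        t = knot
    return out


class TestPkAmount:
    def test_zero_initial_amount(self, typical, drug):
        ind = octsim.IndividualParameters(
            cst_del=typical.cst_del, kin=typical.kin, ec50=typical.ec50,
            cst_min=typical.cst_min, cst0=typical.cst0, pk0=1e-300, h=typical.h)
        assert pk_amount(ind, drug, [], 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_life_definition(self, typical, drug):
        ind = octsim.IndividualParameters(
            cst_del=typical.cst_del, kin=typical.kin, ec50=typical.ec50,
            cst_min=typical.cst_min, cst0=typical.cst0, pk0=0.30, h=typical.h)
        assert pk_amount(ind, drug, [], 9.0) == pytest.approx(0.15, rel=1e-12)

    def test_superposition_matches_ode(self, typical, drug):
        """Analytic bolus superposition equals numerical integration of the
        linear elimination ODE with impulse dosing, on random schedules."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            times = np.sort(rng.uniform(1, 250, size=rng.integers(1, 6)))
            doses = [DoseEvent(float(t), float(rng.uniform(0.5, 4))) for t in times]
            t_eval = np.sort(rng.uniform(0, 300, 20))

            def rhs(t, y):
                return [-drug.k_el * y[0]]

            for t in t_eval:
                y = typical.pk0
                t0 = 0.0
                for d in doses:
                    if d.time <= t:
                        sol = solve_ivp(rhs, (t0, d.time), [y], rtol=1e-12, atol=1e-14)
                        y = sol.y[0][-1] + d.amount
                        t0 = d.time
                sol = solve_ivp(rhs, (t0, t), [y], rtol=1e-12, atol=1e-14)
                expected = sol.y[0][-1] if t > t0 else y
                assert pk_amount(typical, drug, doses, float(t)) == pytest.approx(
                    expected, rel=1e-8)

    def test_rejects_negative_time(self, typical, drug):
        with pytest.raises(ValueError):
            pk_amount(typical, drug, [], -1.0)

    def test_rejects_unsorted_doses(self, typical, drug):
        with pytest.raises(ValueError):
            pk_amount(typical, drug, [DoseEvent(50, 2), DoseEvent(10, 2)], 60.0)


class TestCstDerivative:
    def test_steady_state_without_drug(self, typical):
        assert cst_derivative(typical.cst_max, 0.0, typical) == pytest.approx(0.0, abs=1e-6)

    def test_steady_state_at_full_effect(self, typical):
        d = cst_derivative(typical.cst_min, typical.ec50 * 1e6, typical)
        assert abs(d) < 1e-3 * typical.kin

    def test_half_effect_point(self, typical):
        """At PK = EC50 the stimulation is half-maximal (up to the epsilon
        offset), so dCST/dt = kin - kout (1 + emax/2) cst_min."""
        expected = typical.kin - typical.kout * (1 + typical.emax / 2) * typical.cst_min
        assert cst_derivative(typical.cst_min, typical.ec50, typical) == pytest.approx(
            expected, rel=1e-6)


class TestSimulateTrajectory:
    def test_constant_at_steady_state(self, trial_pop, drug):
        ind = derive_individual(trial_pop, {}, drug)
        ind = octsim.IndividualParameters(
            cst_del=ind.cst_del, kin=ind.kin, ec50=ind.ec50, cst_min=ind.cst_min,
            cst0=ind.cst_max, pk0=1e-300, h=ind.h)
        cst = simulate_trajectory(ind, drug, [], np.linspace(0, 200, 40))
        assert np.allclose(cst, ind.cst_max, atol=1e-5)

    def test_monotone_convergence_to_cst_max(self, trial_pop, drug):
        ind = derive_individual(trial_pop, {}, drug)
        ind = octsim.IndividualParameters(
            cst_del=ind.cst_del, kin=ind.kin, ec50=ind.ec50, cst_min=ind.cst_min,
            cst0=ind.cst_min + 1.0, pk0=1e-300, h=ind.h)
        t_end = 10.0 / ind.kout
        cst = simulate_trajectory(ind, drug, [], np.linspace(0, t_end, 60))
        assert np.all(np.diff(cst) > -1e-9)
        assert cst[-1] == pytest.approx(ind.cst_max, abs=0.1)

    def test_matches_independent_reference(self, drug):
        """Typical revised-population patient under aflibercept 2 mg at days
        28 and 84 agrees with an independent LSODA reference to 0.01 µm."""
        ind = octsim.IndividualParameters(
            cst_del=100.0, kin=float(np.exp(4.0)), ec50=float(np.exp(-1.7)),
            cst_min=226.0, cst0=float(np.exp(5.54)), pk0=0.30, h=float(np.exp(0.78)))
        doses = [DoseEvent(28.0, 2.0), DoseEvent(84.0, 2.0)]
        obs = np.linspace(0, 150, 151)
        ours = simulate_trajectory(ind, drug, doses, obs)
        ref = scipy_reference(ind, drug, doses, obs)
        assert np.max(np.abs(ours - ref)) < 0.01

    def test_never_decreases_below_cst_min(self, trial_pop, drug, design):
        """CST can never be driven below the patient's floor on random
        population draws.  (A patient whose sampled baseline lies below the
        floor starts there and rises, so the lower bound is
        min(cst0, cst_min).)"""
        cohort = octsim.sample_cohort(trial_pop, design, 200, seed=11)
        doses = design.all_doses
        times = np.linspace(0, 308, 45)
        for ind in cohort["aflibercept"]:
            cst = simulate_trajectory(ind, drug, doses, times)
            assert np.all(cst >= min(ind.cst0, ind.cst_min) - 1e-6)
            assert np.all(cst <= max(ind.cst0, ind.cst_max) + 1e-6)


class TestParameterAlgebra:
    def test_typical_ec50_values(self, calib_pop):
        afl = derive_individual(calib_pop, {}, octsim.AFLIBERCEPT)
        ran = derive_individual(calib_pop, {}, octsim.RANIBIZUMAB)
        assert afl.ec50 == pytest.approx(0.18, abs=0.005)
        assert ran.ec50 == pytest.approx(0.022, abs=0.0005)

    def test_log_scale_shift_consistency(self, calib_pop, drug):
        base = derive_individual(calib_pop, {}, drug)
        shifted = derive_individual(calib_pop, {"cst_min": float(np.log(2))}, drug)
        assert shifted.cst_min == pytest.approx(2 * base.cst_min, rel=1e-12)
        assert shifted.kin == pytest.approx(base.kin, rel=1e-12)
        assert shifted.kout == pytest.approx(
            shifted.kin / (shifted.cst_min + shifted.cst_del), rel=1e-12)
        assert shifted.emax == pytest.approx(shifted.cst_del / shifted.cst_min, rel=1e-12)

    def test_unknown_eta_key_rejected(self, calib_pop, drug):
        with pytest.raises(ValueError):
            derive_individual(calib_pop, {"kin": 0.1}, drug)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        kout=st.floats(0.01, 2.0),
        emax=st.floats(0.01, 5.0),
        kin=st.floats(1.0, 200.0),
    )
    def test_reparameterization_round_trip(self, kout, emax, kin):
        """(kout, emax, kin) <-> (cst_del, cst_min, kin) is a bijection on
        the positive orthant."""
        cst_min = kin / (kout * (1 + emax))
        cst_del = emax * cst_min
        assert kin / (cst_min + cst_del) == pytest.approx(kout, rel=1e-12)
        assert cst_del / cst_min == pytest.approx(emax, rel=1e-12)
        assert cst_min + cst_del == pytest.approx(kin / kout, rel=1e-12)

    def test_drug_half_lives(self):
        assert octsim.AFLIBERCEPT.k_el == pytest.approx(np.log(2) / 9.0)
        assert octsim.RANIBIZUMAB.k_el == pytest.approx(np.log(2) / 6.5)
        with pytest.raises(ValueError):
            octsim.DrugSpec(name="bad", half_life=-1.0, theta_ec50=0.0)
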