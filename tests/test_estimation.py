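"""Population-fit tests: likelihood exactness, recovery, multistart, profiles."""

import numpy as np
import pandas as pd
import pytest

import octsim
from octsim import build_schedule, fit_population, multistart, profile_likelihood, simulate_trial
from octsim.estimation import PARAM_NAMES, loess_quadratic, predictions

from conftest import single_arm_design

ALL_FIXED = frozenset(PARAM_NAMES)


def zero_iiv(pop):
    return pop.with_updates(omega={k: 0.0 for k in octsim.RANDOM_EFFECTS})


class TestLikelihoodExactness:
    def test_reduces_to_gaussian_likelihood_without_iiv(self, trial_pop, drug):
        """With all random effects removed and one patient, the approximate
        marginal likelihood equals the closed-form Gaussian residual
        likelihood."""
        pop = zero_iiv(trial_pop)
        ds = simulate_trial(pop, single_arm_design(drug, 1),
                            mode=build_schedule("onsite", 0, 308), seed=44)
        fit = fit_population(ds, drug, pop, fixed=ALL_FIXED)
        pred = predictions(ds, drug, pop)
        rss = float(((pred["DV"] - pred["PRED"]) ** 2).sum())
        n = len(pred)
        expected = n * np.log(2 * np.pi * pop.sigma**2) + rss / pop.sigma**2
        assert fit.ofv == pytest.approx(expected, abs=1e-9 * abs(expected))

    def test_invariant_to_relabeling_and_reordering(self, trial_pop, drug):
        ds = simulate_trial(trial_pop, single_arm_design(drug, 4),
                            mode=build_schedule("onsite", 0, 308), seed=45)
        base = fit_population(ds, drug, trial_pop, fixed=ALL_FIXED).ofv
        df = ds.df.copy()
        df["ID"] = df["ID"].map({1: 40, 2: 17, 3: 23, 4: 5})
        shuffled = octsim.ObservationDataset(
            df.sample(frac=1.0, random_state=0).reset_index(drop=True))
        alt = fit_population(shuffled, drug, trial_pop, fixed=ALL_FIXED).ofv
        assert alt == pytest.approx(base, abs=1e-6)

    def test_duplication_invariance(self, small_onsite_dataset, trial_pop, drug,
                                    small_onsite_fit):
        """Fitting a dataset in which every patient appears twice returns the
        same estimates (the OFV doubles; the maximiser does not move)."""
        ids = np.concatenate([small_onsite_dataset.patient_ids()] * 2)
        doubled = small_onsite_dataset.subset(ids, relabel=True)
        refit = fit_population(doubled, drug, trial_pop)
        np.testing.assert_allclose(
            refit.theta_vector(), small_onsite_fit.theta_vector(), atol=0.02)

    def test_mixed_drug_dataset_rejected(self, small_onsite_dataset, trial_pop, drug):
        df = small_onsite_dataset.df.copy()
        df.loc[df.index[-1], "DRUG"] = "ranibizumab"
        with pytest.raises(ValueError, match="single-drug"):
            fit_population(octsim.ObservationDataset(df), drug, trial_pop)


class TestRecovery:
    def test_noiseless_single_patient_cst_min(self, trial_pop, drug):
        """Noise-free data from one typical patient pin the CST floor when it
        is the only free parameter."""
        pop = zero_iiv(trial_pop).with_updates(sigma=0.5)
        ds = simulate_trial(pop, single_arm_design(drug, 1), mode="home",
                            seed=46, noise_sd=0.0)
        start = pop.with_updates(theta_cst_min=pop.theta_cst_min + 0.05)
        fit = fit_population(ds, drug, start, fixed=ALL_FIXED - {"cst_min"})
        assert fit.converged
        assert fit.param_value("cst_min") == pytest.approx(pop.theta_cst_min, abs=1e-3)

    def test_ofv_history_monotone(self, small_onsite_fit):
        """Accepted iterates decrease the objective (up to the small
        warm-start jitter of the inner mode search)."""
        hist = np.array(small_onsite_fit.ofv_history)
        assert hist.size >= 2
        assert np.all(np.diff(hist) <= 0.05)
        assert hist[-1] < hist[0]

    def test_estimates_near_truth(self, small_onsite_fit, trial_pop):
        """Sanity on the session fitting fixture: structural estimates stay
        within a broad neighbourhood of the generating values."""
        assert abs(small_onsite_fit.param_value("cst_min") - trial_pop.theta_cst_min) < 0.15
        assert abs(small_onsite_fit.param_value("cst0") - trial_pop.theta_cst0) < 0.15


class TestMultistart:
    def test_convex_single_parameter_problem(self, trial_pop, drug):
        """A single free parameter and no random effects make the objective
        an exact Gaussian likelihood: every start reaches the same OFV and
        the waterfall has one plateau."""
        pop = zero_iiv(trial_pop)
        ds = simulate_trial(pop, single_arm_design(drug, 6),
                            mode="onsite", seed=71)
        res = multistart(ds, drug, pop, n_starts=4, dispersion=0.1, seed=2,
                         fixed=ALL_FIXED - {"cst_min"})
        assert np.all(np.diff(res.ofvs) >= 0)
        assert res.ofvs[-1] - res.ofvs[0] < 1e-3
        assert len(res.plateaus) == 1

    def test_most_starts_reach_global_optimum(self, trial_pop, drug):
        """Randomized starts overwhelmingly come back to the same optimum
        region on a 50-patient dataset.  The approximate marginal likelihood
        has genuine nearby local optima (inner-mode switching), so agreement
        is asserted at the method's resolution, not to one OFV unit."""
        ds = simulate_trial(trial_pop, single_arm_design(drug, 50),
                            mode="onsite", seed=303)
        res = multistart(ds, drug, trial_pop, n_starts=8, dispersion=0.3, seed=5)
        assert np.all(np.diff(res.ofvs) >= 0)
        assert np.sum(res.ofvs <= res.ofvs[0] + 10.0) >= 4
        # the top group agrees on the substantive estimate
        floors = [r.param_value("cst_min") for r in res.results[:4]]
        assert np.ptp(floors) < 0.05

    def test_plateau_segmentation_rule(self):
        from octsim.estimation import segment_plateaus
        ofvs = np.array([100.0, 100.4, 100.9, 102.5, 102.6, 110.0])
        assert segment_plateaus(ofvs) == [[0, 1, 2], [3, 4], [5]]

    def test_requires_two_starts(self, small_onsite_dataset, trial_pop, drug):
        with pytest.raises(ValueError):
            multistart(small_onsite_dataset, drug, trial_pop, n_starts=1)


class TestProfiles:
    def test_loess_reproduces_quadratic(self):
        x = np.linspace(-1, 1, 9)
        y = 3.0 + 2.0 * (x - 0.1) ** 2
        fit = loess_quadratic(x, y, x, span=0.9)
        np.testing.assert_allclose(fit, y, atol=1e-8)

    def test_profile_matches_wald_in_quadratic_limit(self, small_onsite_dataset,
                                                     trial_pop, drug):
        """For a single free parameter the profile CI agrees with the Wald
        interval implied by the local OFV curvature."""
        fixed = ALL_FIXED - {"cst_min"}
        fit = fit_population(small_onsite_dataset, drug, trial_pop, fixed=fixed)
        est = fit.param_value("cst_min")
        grid = est + np.linspace(-0.35, 0.35, 9)
        prof = profile_likelihood(small_onsite_dataset, drug, fit, "cst_min",
                                  grid, fixed=fixed)
        assert prof.finite
        assert prof.ci[0] < est < prof.ci[1]
        assert prof.min_ofv <= fit.ofv + 1e-6
        # curvature from the grid points closest to the estimate, where the
        # surface is locally quadratic
        h = prof.grid[1] - prof.grid[0]
        i = int(np.argmin(np.abs(prof.grid - est)))
        c = (prof.ofvs[i - 1] + prof.ofvs[i + 1] - 2 * prof.ofvs[i]) / h**2
        half = (prof.ci[1] - prof.ci[0]) / 2
        assert half == pytest.approx(np.sqrt(3.84 * 2.0 / c), rel=0.2)

    def test_profile_requires_bracketing_grid(self, small_onsite_dataset, trial_pop,
                                              drug, small_onsite_fit):
        est = small_onsite_fit.param_value("cst_min")
        with pytest.raises(ValueError, match="bracket"):
            profile_likelihood(small_onsite_dataset, drug, small_onsite_fit,
                               "cst_min", est + np.linspace(0.5, 1.0, 5))

    def test_open_ci_flagged(self):
        """A profile that never reaches the chi-square threshold inside the
        grid is reported with NaN (open) bounds."""
        from octsim.estimation import LikelihoodProfile
        prof = LikelihoodProfile(
            parameter="x", grid=np.array([0.0, 1.0]), ofvs=np.array([0.0, 0.1]),
            smoothed_grid=np.linspace(0, 1, 5), smoothed_ofv=np.full(5, 0.05),
            level=0.95, ci=(float("nan"), float("nan")), estimate=0.5, min_ofv=0.0)
        assert not prof.finite
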