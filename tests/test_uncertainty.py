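"""Bootstrap-over-fits and Monte Carlo propagation machinery."""

import numpy as np
import pytest

import octsim
from octsim import bootstrap_fits, generate_pool, propagate_endpoint
from octsim.estimation import PARAM_NAMES
from octsim.uncertainty import BootstrapEnsemble

from conftest import single_arm_design

ALL_FIXED = frozenset(PARAM_NAMES)


@pytest.fixture(scope="module")
def small_pool(trial_pop, drug):
    return generate_pool(trial_pop, single_arm_design(drug, 1), mode="onsite",
                         pool_size=40, seed=55)


class TestGeneratePool:
    def test_unique_ids(self, small_pool):
        ids = small_pool.patient_ids()
        assert len(ids) == 40
        assert len(np.unique(ids)) == 40

    def test_regeneration_is_identical(self, trial_pop, drug):
        d = single_arm_design(drug, 1)
        a = generate_pool(trial_pop, d, mode="onsite", pool_size=5, seed=9)
        b = generate_pool(trial_pop, d, mode="onsite", pool_size=5, seed=9)
        assert a.df.equals(b.df)

    def test_resampled_subset_has_n_patients(self, small_pool):
        rng = np.random.default_rng(0)
        chosen = rng.choice(small_pool.patient_ids(), size=15, replace=True)
        sub = small_pool.subset(chosen, relabel=True)
        assert len(sub.patient_ids()) == 15  # duplicates become new subjects


class TestBootstrapFits:
    def test_degenerate_pool_zero_covariance(self, trial_pop, drug):
        """Identical patients (no IIV, no noise) make every resample carry
        the same information, so replicate estimates coincide."""
        pop = trial_pop.with_updates(omega={k: 0.0 for k in octsim.RANDOM_EFFECTS})
        pool = octsim.simulate_trial(pop, single_arm_design(drug, 4),
                                     mode="onsite", seed=66, noise_sd=0.0)
        ens = bootstrap_fits(pool, n=3, reps=3, drug=drug, init=pop, seed=1,
                             fixed=ALL_FIXED - {"cst_min"})
        assert ens.theta_matrix.shape == (3, 1)
        assert np.allclose(np.diag(ens.theta_cov), 0.0, atol=1e-8)

    def test_sd_shrinks_with_sample_size(self, trial_pop, drug):
        """Ensemble SD of the CST-floor estimate decreases when the
        bootstrap draw gets larger (~1/sqrt(n) asymptotically)."""
        pool = generate_pool(trial_pop, single_arm_design(drug, 1),
                             mode="onsite", pool_size=200, seed=77)
        sds = {}
        for n in (10, 40):
            ens = bootstrap_fits(pool, n=n, reps=10, drug=drug, init=trial_pop, seed=3)
            i = ens.theta_names.index("cst_min")
            sds[n] = np.sqrt(ens.theta_cov[i, i])
        assert sds[10] > sds[40]
        assert sds[10] / sds[40] < 5.0

    def test_input_validation(self, small_pool, trial_pop, drug):
        with pytest.raises(ValueError):
            bootstrap_fits(small_pool, n=1, reps=5, drug=drug, init=trial_pop)
        with pytest.raises(ValueError):
            bootstrap_fits(small_pool, n=5, reps=1, drug=drug, init=trial_pop)


def synthetic_ensemble(pop, names, cov):
    """Hand-built ensemble around a known population (no fitting)."""
    mean = np.array([
        pop.theta(n) if not n.startswith("omega_") and n != "sigma"
        else (np.log(pop.sigma) if n == "sigma" else np.log(pop.omega[n[6:]]))
        for n in _canon(names)
    ])
    rng = np.random.default_rng(0)
    mat = rng.multivariate_normal(mean, cov, size=40)
    from octsim.estimation import fit_population  # noqa: F401  (import check)
    return BootstrapEnsemble(
        n_patients=40, replicates=[_StubFit(pop)], theta_names=tuple(names),
        theta_matrix=mat, theta_mean=mean, theta_cov=np.asarray(cov),
        n_failed=0, unreliable=False)


def _canon(names):
    out = []
    for n in names:
        out.append("ec50_aflibercept" if n == "ec50" else n)
    return out


class _StubFit:
    def __init__(self, pop):
        self.theta_hat = pop


class TestPropagateEndpoint:
    def test_zero_covariance_degenerate(self, trial_pop, design, drug):
        names = ("cst_del", "cst_min")
        ens = synthetic_ensemble(trial_pop, names, np.zeros((2, 2)))
        dist = propagate_endpoint(ens, design, drug, n_mc=50, seed=1,
                                  outer_reps=0, init=trial_pop)
        assert np.allclose(dist.samples, dist.samples[0])
        assert dist.se == pytest.approx(0.0, abs=1e-9)
        assert dist.quantile_band[0] <= dist.se <= dist.quantile_band[1]

    def test_delta_method_oracle(self, trial_pop, design, drug):
        """Variance only on the log CST floor: the endpoint SD matches the
        first-order delta method d(endpoint)/d(theta) * sqrt(v)."""
        v = 0.0004
        names = ("cst_min",)
        ens = synthetic_ensemble(trial_pop, names, [[v]])
        dist = propagate_endpoint(ens, design, drug, n_mc=2000, seed=2,
                                  outer_reps=0, init=trial_pop, statistic="typical")
        h = 0.01
        up = trial_pop.with_updates(theta_cst_min=trial_pop.theta_cst_min + h)
        dn = trial_pop.with_updates(theta_cst_min=trial_pop.theta_cst_min - h)
        typ = lambda p: octsim.simulate_trajectory(
            octsim.derive_individual(p, {}, drug), drug, design.all_doses,
            [design.endpoint_day])[0]
        slope = (typ(up) - typ(dn)) / (2 * h)
        assert dist.se == pytest.approx(abs(slope) * np.sqrt(v), rel=0.10)

    def test_seed_reproducibility(self, trial_pop, design, drug):
        names = ("cst_del", "cst_min")
        cov = np.diag([0.01, 0.001])
        ens = synthetic_ensemble(trial_pop, names, cov)
        a = propagate_endpoint(ens, design, drug, n_mc=100, seed=7, outer_reps=5,
                               init=trial_pop)
        b = propagate_endpoint(ens, design, drug, n_mc=100, seed=7, outer_reps=5,
                               init=trial_pop)
        assert np.array_equal(a.samples, b.samples)
        assert a.quantile_band == b.quantile_band

    def test_mean_statistic_exceeds_typical(self, trial_pop, design, drug):
        """Uncertainty in the IIV magnitude contributes to the population
        mean but not to the typical trajectory."""
        names = ("cst_del", "omega_cst_del")
        cov = np.diag([1e-8, 0.05])
        ens = synthetic_ensemble(trial_pop, names, cov)
        typical = propagate_endpoint(ens, design, drug, n_mc=400, seed=3,
                                     outer_reps=0, init=trial_pop, statistic="typical")
        mean = propagate_endpoint(ens, design, drug, n_mc=400, seed=3,
                                  outer_reps=0, init=trial_pop, statistic="mean")
        assert mean.se > 5 * typical.se
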