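import numpy as np
import pytest

import octsim


@pytest.fixture(scope="session")
def calib_pop():
    return octsim.calibration_estimates()


@pytest.fixture(scope="session")
def trial_pop():
    return octsim.trial_population()


@pytest.fixture(scope="session")
def drug():
    return octsim.AFLIBERCEPT


@pytest.fixture(scope="session")
def design():
    return octsim.default_trial_design()


@pytest.fixture(scope="session")
def typical(trial_pop, drug):
    """Typical patient (eta = 0) of the trial-simulation population."""
    return octsim.derive_individual(trial_pop, {}, drug)


def single_arm_design(drug, n):
    base = octsim.default_trial_design()
    return octsim.TrialDesign(
        arms=[(drug.name, drug, 0.0)],
        run_in_doses=base.run_in_doses,
        arm_doses=base.arm_doses,
        endpoint_day=base.endpoint_day,
        n_per_arm=n,
    )


@pytest.fixture(scope="session")
def small_onsite_dataset(trial_pop, drug):
    """12 aflibercept patients, biweekly sampling — the fast fitting fixture."""
    return octsim.simulate_trial(trial_pop, single_arm_design(drug, 12), mode="onsite", seed=202)


@pytest.fixture(scope="session")
def small_onsite_fit(small_onsite_dataset, trial_pop, drug):
    fit = octsim.fit_population(small_onsite_dataset, drug, trial_pop)
    assert fit.converged
    return fit
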