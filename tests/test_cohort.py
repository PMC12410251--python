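"""Cohort synthesis: schedules, sampling distributions, dataset round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import octsim
from octsim import build_schedule, read_dataset, sample_cohort, simulate_trial, write_dataset
from octsim.cohort import ObservationDataset

from conftest import single_arm_design


class TestSchedules:
    def test_onsite_day_count(self):
        sched = build_schedule("onsite", 0, 308)
        assert len(sched.days) == 23
        assert sched.days[0] == 0.0 and sched.days[-1] == 308.0
        assert np.all(np.diff(sched.days) == 14.0)

    def test_home_weekly_counts(self):
        sched = build_schedule("home", 0, 308, seed=3)
        days = np.asarray(sched.days)
        assert 220 <= days.size <= 264
        for w in range(44):
            in_week = days[(days >= 7 * w) & (days < 7 * (w + 1))]
            assert in_week.size in (5, 6)
            assert np.unique(in_week).size == in_week.size

    def test_home_determinism(self):
        a = build_schedule("home", 0, 308, seed=9)
        b = build_schedule("home", 0, 308, seed=9)
        assert a.days == b.days

    def test_endpoint_is_56_days_after_last_dose(self, design):
        last_dose = max(d.time for d in design.all_doses)
        assert design.endpoint_day - last_dose == 56.0  # week 8 after week 36


class TestSampleCohort:
    def test_zero_iiv_gives_typical_patients(self, trial_pop, design, drug):
        pop = trial_pop.with_updates(omega={k: 0.0 for k in octsim.RANDOM_EFFECTS})
        cohort = sample_cohort(pop, design, 5, seed=0)
        typ = octsim.derive_individual(pop, {}, drug)
        for ind in cohort["aflibercept"]:
            assert ind == typ

    def test_law_of_large_numbers_cst_min(self, trial_pop, design):
        n = 1000
        cohort = sample_cohort(trial_pop, design, n, seed=21)
        logs = np.log([ind.cst_min for ind in cohort["aflibercept"]])
        se = np.sqrt(trial_pop.omega["cst_min"] / n)
        assert abs(logs.mean() - np.log(226.0)) < 3 * se

    def test_trial_arm_cst_min_shift(self, trial_pop, design):
        cohort = sample_cohort(trial_pop, design, 800, seed=4)
        log_means = {
            arm: np.mean(np.log([i.cst_min for i in cohort[arm]]))
            for arm in ("trialdrug", "aflibercept")
        }
        assert log_means["aflibercept"] - log_means["trialdrug"] == pytest.approx(
            np.log(226.0) - np.log(186.0), abs=0.02)

    def test_determinism(self, trial_pop, design):
        a = sample_cohort(trial_pop, design, 10, seed=77)
        b = sample_cohort(trial_pop, design, 10, seed=77)
        assert a == b

    def test_lognormal_distribution_ks(self, trial_pop, design):
        """Linear-scale parameters are lognormal with the configured log
        moments (KS non-rejection at alpha = 0.01)."""
        cohort = sample_cohort(trial_pop, design, 10_000, seed=13)
        draws = np.log([ind.cst_del for ind in cohort["aflibercept"]])
        theta = trial_pop.theta_cst_del
        sd = np.sqrt(trial_pop.omega["cst_del"])
        assert stats.kstest(draws, "norm", args=(theta, sd)).pvalue > 0.01


class TestSimulateTrial:
    def test_no_variability_means_identical_records(self, trial_pop, drug):
        pop = trial_pop.with_updates(omega={k: 0.0 for k in octsim.RANDOM_EFFECTS})
        ds = simulate_trial(pop, single_arm_design(drug, 4),
                            mode=build_schedule("onsite", 0, 308), seed=1, noise_sd=0.0)
        obs = ds.observations.pivot(index="ID", columns="TIME", values="DV")
        assert np.allclose(obs.to_numpy(), obs.to_numpy()[0], atol=1e-9)

    def test_noise_variance_matches_error_model(self, trial_pop, drug):
        """Across patients with zero IIV, the endpoint spread equals the
        additive residual variance (sigma^2 = 30.25 µm^2)."""
        pop = trial_pop.with_updates(omega={k: 0.0 for k in octsim.RANDOM_EFFECTS})
        ds = simulate_trial(pop, single_arm_design(drug, 2000),
                            mode=build_schedule("onsite", 0, 308), seed=8)
        vals = ds.endpoint_values(308.0)
        assert vals.var(ddof=1) == pytest.approx(5.5**2, rel=0.15)

    def test_modes_share_noise_free_trajectories(self, trial_pop, design, drug):
        """The same underlying patients observed under both schedules agree
        at shared days when noise is switched off."""
        cohort = sample_cohort(trial_pop, design, 3, seed=31)
        home = simulate_trial(trial_pop, design, mode="home", seed=1,
                              cohort=cohort, noise_sd=0.0)
        onsite = simulate_trial(trial_pop, design, mode="onsite", seed=2,
                                cohort=cohort, noise_sd=0.0)
        merged = home.observations.merge(
            onsite.observations, on=["ID", "TIME"], suffixes=("_h", "_o"))
        assert len(merged) > 0
        assert np.allclose(merged["DV_h"], merged["DV_o"], atol=1e-9)

    def test_endpoint_always_observed(self, trial_pop, design):
        ds = simulate_trial(trial_pop, design, mode="home", seed=3,
                            cohort=sample_cohort(trial_pop, design, 2, seed=3))
        for pid in ds.patient_ids():
            pat = ds.observations[ds.observations["ID"] == pid]
            assert np.isclose(pat["TIME"].max(), 308.0)


class TestDatasetIO:
    def _small(self, trial_pop, drug):
        return simulate_trial(trial_pop, single_arm_design(drug, 2),
                              mode=build_schedule("onsite", 0, 308), seed=5)

    def test_round_trip(self, tmp_path, trial_pop, drug):
        ds = self._small(trial_pop, drug)
        path = tmp_path / "data.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        pd.testing.assert_frame_equal(ds.df, back.df)

    def test_dose_sorts_before_observation_at_same_time(self):
        df = pd.DataFrame({
            "ID": [1, 1], "TIME": [28.0, 28.0], "DV": [300.0, np.nan],
            "AMT": [np.nan, 2.0], "EVID": [0, 1], "ARM": ["a", "a"], "DRUG": ["d", "d"],
        })
        from octsim.cohort import _sort_records
        out = _sort_records(df)
        assert list(out["EVID"]) == [1, 0]

    def test_empty_dataset_round_trip(self, tmp_path):
        empty = ObservationDataset(pd.DataFrame(
            columns=["ID", "TIME", "DV", "AMT", "EVID", "ARM", "DRUG"]))
        path = tmp_path / "empty.csv"
        write_dataset(empty, path)
        back = read_dataset(path)
        assert back.df.empty
        assert list(back.df.columns) == ["ID", "TIME", "DV", "AMT", "EVID", "ARM", "DRUG"]

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ID,TIME,DV,AMT,EVID,ARM,DRUG\n1,0.0,250.0,.,0,a,d\n1,oops,251.0,.,0,a,d\n")
        with pytest.raises(ValueError, match="line 3"):
            read_dataset(path)
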