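"""Virtual-cohort generation and NONMEM-style trial datasets.

Implements the two-arm virtual trial: an aflibercept run-in (2 mg IVT at days
28 and 84 for everybody), randomization to trial drug vs. aflibercept with
q8w dosing at days 140/196/252, and the week-44 endpoint at day 308 — eight
weeks after the last dose.  The trial drug is kinetically identical to
aflibercept; its only effect is a 40 µm lower population-mean CST floor
(CST_MIN 186 vs. 226 µm).

Observations are taken either on a home-monitoring schedule (five or six
randomly placed measurements per calendar week) or an on-site schedule
(every 14 days), with additive Gaussian residual noise (sigma = 5.5 µm by
default).  Datasets are long-format event records (ID, TIME, DV, AMT, EVID,
ARM, DRUG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .params import (
    AFLIBERCEPT,
    RANDOM_EFFECTS,
    DoseEvent,
    DrugSpec,
    IndividualParameters,
    PopulationParameters,
    derive_individual,
)

__all__ = [
    "TrialDesign",
    "SamplingSchedule",
    "ObservationDataset",
    "TRIALDRUG",
    "default_trial_design",
    "sample_cohort",
    "build_schedule",
    "simulate_trial",
    "write_dataset",
    "read_dataset",
]

#: Hypothetical investigational drug: kinetics and potency of aflibercept.
TRIALDRUG = DrugSpec(name="trialdrug", half_life=9.0, theta_ec50=-1.7)

_COLUMNS = ["ID", "TIME", "DV", "AMT", "EVID", "ARM", "DRUG"]


@dataclass(frozen=True)
class TrialDesign:
    """Arms, dosing events and endpoint of the virtual trial.

    ``arms`` is a list of ``(arm_id, DrugSpec, cst_min_shift)`` where the
    shift (µm) is applied to the arm's population-mean CST_MIN on the linear
    scale before log-transforming.
    """

    arms: list[tuple[str, DrugSpec, float]]
    run_in_doses: list[DoseEvent]
    arm_doses: list[DoseEvent]
    endpoint_day: float = 308.0
    n_per_arm: int = 1000

    def __post_init__(self) -> None:
        last_dose = max(
            [d.time for d in self.run_in_doses] + [d.time for d in self.arm_doses]
        )
        if self.endpoint_day <= last_dose:
            raise ValueError("endpoint_day must come after the last dose")

    @property
    def all_doses(self) -> list[DoseEvent]:
        return sorted(self.run_in_doses + self.arm_doses, key=lambda d: d.time)

    def arm_population(self, pop: PopulationParameters, arm_id: str) -> PopulationParameters:
        """Population parameters with the arm's CST_MIN shift applied."""
        shift = dict((a, s) for a, _, s in self.arms)[arm_id]
        if shift == 0.0:
            return pop
        shifted = math.exp(pop.theta_cst_min) + shift
        if shifted <= 0:
            raise ValueError("cst_min_shift drives the CST floor non-positive")
        return pop.with_updates(theta_cst_min=math.log(shifted))


def default_trial_design(n_per_arm: int = 1000) -> TrialDesign:
    """The reference two-arm scheme: run-in at weeks 4/12, q8w dosing to week
    36, endpoint at week 44 (day 308)."""
    return TrialDesign(
        arms=[("trialdrug", TRIALDRUG, -40.0), ("aflibercept", AFLIBERCEPT, 0.0)],
        run_in_doses=[DoseEvent(28.0, 2.0), DoseEvent(84.0, 2.0)],
        arm_doses=[DoseEvent(140.0, 2.0), DoseEvent(196.0, 2.0), DoseEvent(252.0, 2.0)],
        endpoint_day=308.0,
        n_per_arm=n_per_arm,
    )


@dataclass(frozen=True)
class SamplingSchedule:
    """Observation days for one patient.

    ``home``: five or six distinct days per calendar week; ``onsite``: every
    14 days from day 0.
    """

    mode: str
    days: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("home", "onsite"):
            raise ValueError("mode must be 'home' or 'onsite'")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")


def build_schedule(
    mode: str,
    start_day: float = 0.0,
    end_day: float = 308.0,
    seed: int | np.random.Generator | None = None,
) -> SamplingSchedule:
    """Draw one observation schedule on ``[start_day, end_day)`` / ``[.., end_day]``.

    Home monitoring: for each calendar week in ``[start_day, end_day)`` a fair
    coin picks 5 or 6 observations, placed on distinct days of that week.
    On-site: fixed visits every 14 days from ``start_day`` through ``end_day``
    inclusive.
    """
    if end_day <= start_day:
        raise ValueError("end_day must exceed start_day")
    if mode == "onsite":
        days = np.arange(start_day, end_day + 1e-9, 14.0)
        return SamplingSchedule(mode="onsite", days=tuple(float(d) for d in days))
    if mode != "home":
        raise ValueError("mode must be 'home' or 'onsite'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days: list[float] = []
    week_start = start_day
    while week_start < end_day:
        week_days = np.arange(week_start, min(week_start + 7.0, end_day))
        k = min(5 + int(rng.integers(0, 2)), week_days.size)
        chosen = rng.choice(week_days, size=k, replace=False)
        days.extend(float(d) for d in np.sort(chosen))
        week_start += 7.0
    return SamplingSchedule(mode="home", days=tuple(days))


def sample_cohort(
    pop: PopulationParameters,
    design: TrialDesign,
    n: int,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 10,
) -> dict[str, list[IndividualParameters]]:
    """Draw ``n`` patients per arm from the population distribution.

    The five random effects are sampled independently from N(0, omega_k)
    (variance convention, diagonal Omega); the arm's CST_MIN shift is applied
    to the population mean before sampling.  Arms share no draws.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cohort: dict[str, list[IndividualParameters]] = {}
    for arm_id, drug, _shift in design.arms:
        arm_pop = design.arm_population(pop, arm_id)
        sds = np.sqrt(arm_pop.omega_vector())
        patients = []
        for _ in range(n):
            for _attempt in range(max_retries):
                draws = rng.normal(0.0, sds)
                if np.all(np.isfinite(draws)):
                    break
            else:
                raise RuntimeError("could not draw finite random effects")
            eta = dict(zip(RANDOM_EFFECTS, draws))
            patients.append(derive_individual(arm_pop, eta, drug))
        cohort[arm_id] = patients
    return cohort


@dataclass
class ObservationDataset:
    """Long-format event records of one simulated trial (both arms).

    ``df`` columns: ID (int), TIME (days), DV (observed CST, µm; NaN on dose
    rows), AMT (mg; NaN on observation rows), EVID (0 observation / 1 dose),
    ARM, DRUG.  Rows are sorted by (ID, TIME) with doses before observations
    at ties.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")

    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    @property
    def arms(self) -> list[str]:
        return sorted(self.df["ARM"].dropna().unique())

    def patient_ids(self, arm: str | None = None) -> np.ndarray:
        df = self.df if arm is None else self.df[self.df["ARM"] == arm]
        return np.sort(df["ID"].unique())

    def for_arm(self, arm: str) -> "ObservationDataset":
        return ObservationDataset(self.df[self.df["ARM"] == arm].reset_index(drop=True))

    def subset(self, ids: np.ndarray, relabel: bool = False) -> "ObservationDataset":
        """Records of the given patients; with ``relabel`` duplicates in
        ``ids`` become distinct new subjects (case-resampling bootstrap)."""
        frames = []
        for new_id, pid in enumerate(ids, start=1):
            block = self.df[self.df["ID"] == pid]
            if relabel:
                block = block.assign(ID=new_id)
            frames.append(block)
        return ObservationDataset(pd.concat(frames, ignore_index=True))

    def endpoint_values(self, day: float, arm: str | None = None) -> np.ndarray:
        """Observed (noisy) CST at the endpoint day, one value per patient."""
        obs = self.observations
        if arm is not None:
            obs = obs[obs["ARM"] == arm]
        at = obs[np.isclose(obs["TIME"], day)]
        return at.sort_values("ID")["DV"].to_numpy(dtype=float)


def _sort_records(df: pd.DataFrame) -> pd.DataFrame:
    # doses (EVID=1) precede observations (EVID=0) at the same time
    return (
        df.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False])
        .reset_index(drop=True)
    )


def simulate_trial(
    pop: PopulationParameters,
    design: TrialDesign,
    mode: str | SamplingSchedule = "home",
    seed: int | np.random.Generator | None = None,
    cohort: dict[str, list[IndividualParameters]] | None = None,
    include_endpoint: bool = True,
    noise_sd: float | None = None,
    rtol: float = 1.0e-8,
    atol: float = 1.0e-8,
) -> ObservationDataset:
    """Simulate one two-arm trial dataset.

    Per patient: draw individual parameters (unless a pre-sampled ``cohort``
    is supplied), draw an observation schedule (per patient for home
    monitoring, common for on-site), integrate the noise-free trajectory and
    add i.i.d. N(0, sigma^2) residual noise.  The endpoint day is always
    observed when ``include_endpoint`` is set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = pop.sigma if noise_sd is None else noise_sd
    if cohort is None:
        cohort = sample_cohort(pop, design, design.n_per_arm, rng)

    dose_events = design.all_doses
    dose_t = np.array([d.time for d in dose_events])
    dose_a = np.array([d.amount for d in dose_events])

    records = []
    pid = 0
    for arm_id, drug, _shift in design.arms:
        for indiv in cohort[arm_id]:
            pid += 1
            if isinstance(mode, SamplingSchedule):
                sched = mode
            elif mode == "home":
                sched = build_schedule("home", 0.0, design.endpoint_day, rng)
            else:
                sched = build_schedule(mode, 0.0, design.endpoint_day, rng)
            days = np.asarray(sched.days, dtype=float)
            if include_endpoint and not np.any(np.isclose(days, design.endpoint_day)):
                days = np.append(days, design.endpoint_day)
            cst = _kernels.simulate_cst(
                indiv.cst_del,
                indiv.kin,
                indiv.ec50,
                indiv.cst_min,
                indiv.cst0,
                indiv.pk0,
                indiv.h,
                drug.k_el,
                dose_t,
                dose_a,
                days,
                rtol,
                atol,
            )
            if np.any(np.isnan(cst)):
                raise RuntimeError(f"integration failed for patient {pid} in arm {arm_id}")
            dv = cst + rng.normal(0.0, sigma, size=days.size)
            for t, v in zip(days, dv):
                records.append((pid, float(t), float(v), np.nan, 0, arm_id, drug.name))
            for t, a in zip(dose_t, dose_a):
                records.append((pid, float(t), np.nan, float(a), 1, arm_id, drug.name))
    df = pd.DataFrame.from_records(records, columns=_COLUMNS)
    return ObservationDataset(_sort_records(df))


def write_dataset(dataset: ObservationDataset, path) -> None:
    """Serialize to CSV (columns ID,TIME,DV,AMT,EVID,ARM,DRUG; missing as '.')."""
    out = dataset.df.copy()
    for col in ("DV", "AMT"):
        out[col] = out[col].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    out["TIME"] = out["TIME"].map(lambda v: repr(float(v)))
    out.to_csv(path, index=False)


def read_dataset(path) -> ObservationDataset:
    """Parse an event-record CSV written by :func:`write_dataset`.

    Malformed numeric fields raise ``ValueError`` naming the offending line
    (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    def _numeric(col: str, allow_missing: bool) -> pd.Series:
        raw = df[col].replace(".", np.nan) if allow_missing else df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & ~(raw.isna() if allow_missing else pd.Series(False, index=df.index))
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"malformed value in column {col} at line {line}")
        return parsed

    out = pd.DataFrame(
        {
            "ID": _numeric("ID", False).astype(int),
            "TIME": _numeric("TIME", False),
            "DV": _numeric("DV", True),
            "AMT": _numeric("AMT", True),
            "EVID": _numeric("EVID", False).astype(int),
            "ARM": df["ARM"],
            "DRUG": df["DRUG"],
        }
    )
    return ObservationDataset(out)
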