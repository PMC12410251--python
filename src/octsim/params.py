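"""Population and individual parameters of the CST indirect-response model.

The model describes central subfield thickness (CST, µm) in neovascular AMD
eyes under intravitreal anti-VEGF bolus dosing.  All structural parameters are
handled on the natural-log scale at the population level; an individual's
linear-scale parameter is ``exp(theta) * exp(eta)`` with ``eta ~ N(0, omega)``
(variance convention, diagonal).  Random effects exist on five parameters:
CST_DEL, EC50 (shared between drugs), CST_MIN, CST_0 and PK_0.  The residual
error SD ``sigma`` (µm) is the only linear-scale parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Names of the random effects, in canonical order.
RANDOM_EFFECTS: tuple[str, ...] = ("cst_del", "ec50", "cst_min", "cst0", "pk0")

#: Names of the log-scale fixed effects, in canonical order.
THETA_NAMES: tuple[str, ...] = (
    "cst_del",
    "kin",
    "ec50_aflibercept",
    "ec50_ranibizumab",
    "cst_min",
    "cst0",
    "pk0",
    "h",
)


@dataclass(frozen=True)
class DrugSpec:
    """An intravitreally injected anti-VEGF agent.

    Elimination from the vitreous is first order with a fixed, drug-specific
    half-life; ``k_el = ln 2 / half_life``.  ``theta_ec50`` is the log-scale
    population potency (log mg) used when deriving individual parameters.
    """

    name: str
    half_life: float  # days
    theta_ec50: float  # log(mg)

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")

    @property
    def k_el(self) -> float:
        """First-order elimination rate constant, 1/day."""
        return math.log(2.0) / self.half_life


@dataclass(frozen=True)
class DoseEvent:
    """A bolus intravitreal dose: full amount enters the vitreous at `time`."""

    time: float  # days since trial start
    amount: float  # mg

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects (log scale), random-effect variances and residual SD.

    ``omega`` maps random-effect name -> variance of the log-scale effect.
    Keys must be exactly :data:`RANDOM_EFFECTS`; the synthesis rate K_IN and
    the Hill coefficient H carry no inter-individual variability.
    """

    theta_cst_del: float  # log(µm)
    theta_kin: float  # log(µm/day)
    theta_ec50_aflibercept: float  # log(mg)
    theta_ec50_ranibizumab: float  # log(mg)
    theta_cst_min: float  # log(µm)
    theta_cst0: float  # log(µm)
    theta_pk0: float  # log(mg)
    theta_h: float  # log(dimensionless)
    sigma: float  # µm, linear scale
    omega: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if set(self.omega) != set(RANDOM_EFFECTS):
            raise ValueError(
                f"omega keys must be exactly {set(RANDOM_EFFECTS)}, got {set(self.omega)}"
            )
        if any(v < 0 for v in self.omega.values()):
            raise ValueError("omega entries must be non-negative variances")

    def theta(self, name: str) -> float:
        """Log-scale fixed effect by short name (see :data:`THETA_NAMES`)."""
        return getattr(self, f"theta_{name}")

    def theta_vector(self) -> np.ndarray:
        """The eight fixed effects as an array in canonical order."""
        return np.array([self.theta(n) for n in THETA_NAMES], dtype=float)

    def omega_vector(self) -> np.ndarray:
        """Random-effect variances in canonical order."""
        return np.array([self.omega[n] for n in RANDOM_EFFECTS], dtype=float)

    def with_updates(self, **kwargs) -> "PopulationParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class IndividualParameters:
    """Linear-scale parameters of one simulated patient.

    ``kout``, ``emax`` and ``cst_max`` are derived:

        kout    = kin / (cst_min + cst_del)
        emax    = cst_del / cst_min
        cst_max = cst_min + cst_del

    which makes the remaining parameters independent and guarantees that the
    CST trajectory can never undershoot ``cst_min`` nor (from below) overshoot
    ``cst_max``.
    """

    cst_del: float  # µm
    kin: float  # µm/day
    ec50: float  # mg (drug-specific)
    cst_min: float  # µm
    cst0: float  # µm
    pk0: float  # mg
    h: float  # dimensionless

    def __post_init__(self) -> None:
        for name in ("cst_del", "kin", "ec50", "cst_min", "cst0", "pk0", "h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kout(self) -> float:
        """First-order CST loss rate, 1/day."""
        return self.kin / (self.cst_min + self.cst_del)

    @property
    def emax(self) -> float:
        """Maximum fractional stimulation of CST loss."""
        return self.cst_del / self.cst_min

    @property
    def cst_max(self) -> float:
        """Untreated steady-state CST, µm."""
        return self.cst_min + self.cst_del


def derive_individual(
    pop: PopulationParameters,
    eta: dict[str, float] | None,
    drug: DrugSpec,
) -> IndividualParameters:
    """Map population parameters + random effects to one patient.

    Each linear-scale parameter is ``exp(theta + eta)``; missing eta keys are
    treated as zero (typical value).  The EC50 uses the drug-specific theta
    with the single shared EC50 random effect.
    """
    eta = dict(eta or {})
    unknown = set(eta) - set(RANDOM_EFFECTS)
    if unknown:
        raise ValueError(f"unknown random-effect keys: {sorted(unknown)}")
    e = {k: eta.get(k, 0.0) for k in RANDOM_EFFECTS}
    return IndividualParameters(
        cst_del=math.exp(pop.theta_cst_del + e["cst_del"]),
        kin=math.exp(pop.theta_kin),
        ec50=math.exp(drug.theta_ec50 + e["ec50"]),
        cst_min=math.exp(pop.theta_cst_min + e["cst_min"]),
        cst0=math.exp(pop.theta_cst0 + e["cst0"]),
        pk0=math.exp(pop.theta_pk0 + e["pk0"]),
        h=math.exp(pop.theta_h),
    )


#: Aflibercept: 9-day vitreous half-life, log-potency −1.7 (0.18 mg).
AFLIBERCEPT = DrugSpec(name="aflibercept", half_life=9.0, theta_ec50=-1.7)

#: Ranibizumab: 6.5-day vitreous half-life, log-potency −3.8 (0.022 mg).
RANIBIZUMAB = DrugSpec(name="ranibizumab", half_life=6.5, theta_ec50=-3.8)


def calibration_estimates() -> PopulationParameters:
    """Best-fit population estimates of the home-OCT calibration model.

    These are the final-model estimates (log scale except sigma): CST_DEL 3.6,
    K_IN 4.0, EC50 −1.7/−3.8, CST_MIN 5.42, CST_0 5.54, PK_0 −1.2, H 0.78,
    sigma 5.5 µm, with diagonal random-effect variances 1.02 (CST_DEL),
    2.8 (EC50, shared), 0.033 (CST_MIN), 0.038 (CST_0) and 4.5 (PK_0).
    """
    return PopulationParameters(
        theta_cst_del=3.6,
        theta_kin=4.0,
        theta_ec50_aflibercept=-1.7,
        theta_ec50_ranibizumab=-3.8,
        theta_cst_min=5.42,
        theta_cst0=5.54,
        theta_pk0=-1.2,
        theta_h=0.78,
        sigma=5.5,
        omega={"cst_del": 1.02, "ec50": 2.8, "cst_min": 0.033, "cst0": 0.038, "pk0": 4.5},
    )


#: Population-mean CST_DEL (µm, arithmetic scale) used in trial simulations.
TRIAL_CST_DEL_MEAN = 100.0


def trial_population(cst_del_mean: float = TRIAL_CST_DEL_MEAN) -> PopulationParameters:
    """Population used for virtual-trial simulation.

    Identical to :func:`calibration_estimates` except that the CST_DEL
    population mean is raised to ``cst_del_mean`` µm (default 100), reflecting
    eyes with active disease as enrolled in interventional trials rather than
    the observational both-eyes cohort.  The mean is the arithmetic mean of
    the lognormal, so ``theta = ln(mean) - omega/2``.
    """
    pop = calibration_estimates()
    theta = math.log(cst_del_mean) - pop.omega["cst_del"] / 2.0
    return pop.with_updates(theta_cst_del=theta)
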