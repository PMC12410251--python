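"""Structured YAML configuration for populations and trial designs."""

from __future__ import annotations

import yaml

from .cohort import TrialDesign, default_trial_design
from .params import (
    AFLIBERCEPT,
    RANIBIZUMAB,
    DoseEvent,
    DrugSpec,
    PopulationParameters,
    trial_population,
)

__all__ = ["population_to_dict", "population_from_dict", "design_to_dict",
           "design_from_dict", "load_config", "save_config", "default_config"]

_KNOWN_DRUGS = {d.name: d for d in (AFLIBERCEPT, RANIBIZUMAB)}


def population_to_dict(pop: PopulationParameters) -> dict:
    return {
        "theta": {
            "cst_del": pop.theta_cst_del,
            "kin": pop.theta_kin,
            "ec50_aflibercept": pop.theta_ec50_aflibercept,
            "ec50_ranibizumab": pop.theta_ec50_ranibizumab,
            "cst_min": pop.theta_cst_min,
            "cst0": pop.theta_cst0,
            "pk0": pop.theta_pk0,
            "h": pop.theta_h,
        },
        "omega": dict(pop.omega),
        "sigma": pop.sigma,
    }


def population_from_dict(d: dict) -> PopulationParameters:
    theta = d["theta"]
    return PopulationParameters(
        **{f"theta_{k}": float(v) for k, v in theta.items()},
        sigma=float(d["sigma"]),
        omega={k: float(v) for k, v in d["omega"].items()},
    )


def _drug_to_dict(drug: DrugSpec) -> dict:
    return {"name": drug.name, "half_life": drug.half_life, "theta_ec50": drug.theta_ec50}


def design_to_dict(design: TrialDesign) -> dict:
    return {
        "arms": [
            {"arm_id": a, "drug": _drug_to_dict(drug), "cst_min_shift": shift}
            for a, drug, shift in design.arms
        ],
        "run_in_doses": [[d.time, d.amount] for d in design.run_in_doses],
        "arm_doses": [[d.time, d.amount] for d in design.arm_doses],
        "endpoint_day": design.endpoint_day,
        "n_per_arm": design.n_per_arm,
    }


def design_from_dict(d: dict) -> TrialDesign:
    arms = []
    for a in d["arms"]:
        drug = DrugSpec(**a["drug"]) if isinstance(a["drug"], dict) else _KNOWN_DRUGS[a["drug"]]
        arms.append((a["arm_id"], drug, float(a["cst_min_shift"])))
    return TrialDesign(
        arms=arms,
        run_in_doses=[DoseEvent(t, amt) for t, amt in d["run_in_doses"]],
        arm_doses=[DoseEvent(t, amt) for t, amt in d["arm_doses"]],
        endpoint_day=float(d["endpoint_day"]),
        n_per_arm=int(d["n_per_arm"]),
    )


def default_config(seed: int = 1) -> dict:
    """Reference configuration: trial-simulation population and Fig-style
    two-arm q8w design."""
    return {
        "population": population_to_dict(trial_population()),
        "design": design_to_dict(default_trial_design()),
        "seed": seed,
    }


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out = dict(cfg)
    if "population" in cfg:
        out["population"] = population_from_dict(cfg["population"])
    if "design" in cfg:
        out["design"] = design_from_dict(cfg["design"])
    return out
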