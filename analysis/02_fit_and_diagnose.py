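#!/usr/bin/env python
"""Fit the population model to simulated data and check its adequacy.

Fits one aflibercept arm (60 patients, on-site schedule by default),
verifies the optimum with a multistart waterfall, profiles the structural
parameters for identifiability, and runs the prediction-corrected VPC and
residual diagnostics.

Writes under results/:
  fit_estimates.csv     estimates vs. generating values, with profile CIs
  waterfall.csv/.png    sorted multistart objective values
  profiles.png          profile-likelihood curves
  pcvpc.csv/.png        binned percentiles of the prediction-corrected VPC
  residual_summary.csv  standardized-residual summary
"""

import pathlib
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import octsim
from octsim.estimation import segment_plateaus

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
QUICK = "--quick" in sys.argv

SEED = 2
N_PATIENTS = 20 if QUICK else 60
N_STARTS = 4 if QUICK else 10
N_SIM_VPC = 200 if QUICK else 500

pop = octsim.trial_population()
drug = octsim.AFLIBERCEPT
base = octsim.default_trial_design()
design = octsim.TrialDesign(arms=[(drug.name, drug, 0.0)], run_in_doses=base.run_in_doses,
                            arm_doses=base.arm_doses, endpoint_day=308.0,
                            n_per_arm=N_PATIENTS)
dataset = octsim.simulate_trial(pop, design, mode="onsite", seed=SEED)
print(f"fitting {N_PATIENTS} patients, {len(dataset.observations)} observations")

fit = octsim.fit_population(dataset, drug, pop)
print(f"converged={fit.converged} OFV={fit.ofv:.1f} evals={fit.n_function_evals}")

water = octsim.multistart(dataset, drug, pop, n_starts=N_STARTS, dispersion=0.4,
                          seed=SEED + 1)
plateaus = segment_plateaus(water.ofvs)
pd.DataFrame({"rank": np.arange(1, len(water.ofvs) + 1), "ofv": water.ofvs}).to_csv(
    OUT / "waterfall.csv", index=False)
print(f"multistart: best OFV {water.ofvs[0]:.1f}, "
      f"{sum(o <= water.ofvs[0] + 5 for o in water.ofvs)}/{len(water.ofvs)} starts "
      f"within 5 units of the best")

best = water.results[0] if water.ofvs[0] < fit.ofv else fit

widths = {"cst_del": 0.7, "kin": 0.2, "ec50": 1.0, "cst_min": 0.1,
          "cst0": 0.12, "pk0": 1.0, "h": 0.3}
truth = {"cst_del": pop.theta_cst_del, "kin": pop.theta_kin,
         "ec50": pop.theta_ec50_aflibercept, "cst_min": pop.theta_cst_min,
         "cst0": pop.theta_cst0, "pk0": pop.theta_pk0, "h": pop.theta_h}
rows, profs = [], {}
for name, w in widths.items():
    est = best.param_value(name)
    prof = octsim.profile_likelihood(dataset, drug, best, name,
                                     est + np.linspace(-w, w, 7))
    profs[name] = prof
    rows.append({"parameter": name, "estimate": est, "truth": truth[name],
                 "ci_low": prof.ci[0], "ci_high": prof.ci[1],
                 "finite": prof.finite,
                 "covered": prof.ci[0] <= truth[name] <= prof.ci[1]})
    print(f"  {name:8s} est {est:7.3f} truth {truth[name]:7.3f} "
          f"95% CI [{prof.ci[0]:7.3f}, {prof.ci[1]:7.3f}]")
pd.DataFrame(rows).to_csv(OUT / "fit_estimates.csv", index=False)

fig, axes = plt.subplots(2, 4, figsize=(13, 6))
for ax, (name, prof) in zip(axes.ravel(), profs.items()):
    ax.plot(prof.smoothed_grid, prof.smoothed_ofv - prof.min_ofv, "-", lw=1)
    ax.plot(prof.grid, prof.ofvs - prof.min_ofv, "x", ms=4)
    ax.axhline(3.84, color="grey", ls="--", lw=0.8)
    ax.axvline(truth[name], color="red", lw=0.8)
    ax.set_title(name)
    ax.set_ylim(-0.5, 12)
axes[-1, -1].plot(np.arange(1, len(water.ofvs) + 1), water.ofvs - water.ofvs[0], "o-")
axes[-1, -1].set_title(f"waterfall ({len(plateaus)} plateaus)")
fig.tight_layout()
fig.savefig(OUT / "profiles.png", dpi=120)

vpc = octsim.pcvpc(dataset, best, drug, n_sim=N_SIM_VPC, bins=10, seed=SEED + 2)
vrows = []
for b, (lo, hi, n_obs) in enumerate(vpc.bins):
    p10, p50, p90 = vpc.simulated_percentiles[b]
    o10, o50, o90 = vpc.observed_percentiles[b]
    vrows.append({"t_low": lo, "t_high": hi, "n_obs": n_obs,
                  "sim_p10": p10, "sim_p50": p50, "sim_p90": p90,
                  "obs_p10": o10, "obs_p50": o50, "obs_p90": o90})
vdf = pd.DataFrame(vrows)
vdf.to_csv(OUT / "pcvpc.csv", index=False)

fig, ax = plt.subplots(figsize=(7, 4))
mid = (vdf["t_low"] + vdf["t_high"]) / 2 / 7.0
ax.fill_between(mid, vdf["sim_p10"], vdf["sim_p90"], alpha=0.3, label="simulated 10-90%")
ax.plot(mid, vdf["sim_p50"], "-", label="simulated median")
for q, marker in (("obs_p10", "v"), ("obs_p50", "o"), ("obs_p90", "^")):
    ax.plot(mid, vdf[q], marker, color="k", ms=4)
ax.set_xlabel("week")
ax.set_ylabel("prediction-corrected CST (µm)")
ax.legend()
fig.tight_layout()
fig.savefig(OUT / "pcvpc.png", dpi=120)

resid = octsim.residual_diagnostics(dataset, best, drug)
pd.DataFrame([resid["summary"]]).to_csv(OUT / "residual_summary.csv", index=False)
print("residual summary:", resid["summary"])
print(f"wrote fit/diagnostic tables and figures under {OUT}/")
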