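#!/usr/bin/env python
"""Determine the per-arm sample size for 95% detection in each setting.

Reads the endpoint-SE curves written by 03_error_propagation.py, forms the
two-sample z-score z = delta / sqrt(SE1^2 + SE2^2) on the n grid, and
reports the smallest n with z >= 1.96, with the quantile-ribbon crossings as
an interval.

Writes under results/:
  sample_size.csv   n*, band crossings and the relative reduction
  z_curves.png      z-score curves with the 1.96 threshold
"""

import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from octsim import power

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
curves = pd.read_csv(OUT / "se_curves.csv")

summary = []
z_curves = {}
for setting, block in curves.groupby("setting", sort=False):
    arms = sorted(block["arm"].unique())
    a0 = block[block["arm"] == arms[0]].sort_values("n")
    a1 = block[block["arm"] == arms[1]].sort_values("n")
    n_grid = a0["n"].to_numpy()
    delta = float(a0["delta_um"].iloc[0])
    band0 = a0[["se_q2p5", "se_q97p5"]].to_numpy()
    band1 = a1[["se_q2p5", "se_q97p5"]].to_numpy()
    has_band = not np.isnan(band0).all()
    curve = power.find_n_star(
        n_grid, delta, a0["se_um"].to_numpy(), a1["se_um"].to_numpy(),
        band0 if has_band else None, band1 if has_band else None)
    z_curves[setting] = curve
    summary.append({
        "setting": setting, "delta_um": delta, "n_star": curve.n_star,
        "n_star_optimistic": curve.n_star_band[0],
        "n_star_pessimistic": curve.n_star_band[1],
        "max_z": curve.max_z,
    })
    print(f"{setting:9s} delta={delta:5.1f} µm  n* = {curve.n_star} "
          f"(band {curve.n_star_band[0]}-{curve.n_star_band[1]})")

df = pd.DataFrame(summary).set_index("setting")
if {"classical", "home"} <= set(df.index):
    red = 1.0 - df.loc["home", "n_star"] / df.loc["classical", "n_star"]
    df["reduction_vs_classical"] = np.nan
    df.loc["home", "reduction_vs_classical"] = red
    print(f"home monitoring reduces the required sample size by {red:.0%} "
          f"relative to the classical baseline")
df.to_csv(OUT / "sample_size.csv")

fig, axes = plt.subplots(1, len(z_curves), figsize=(4.3 * len(z_curves), 4), sharey=True)
for ax, (setting, curve) in zip(np.atleast_1d(axes), z_curves.items()):
    ax.plot(curve.n_grid, curve.z, "-", label="z")
    ax.fill_between(curve.n_grid, curve.z_band[:, 1], curve.z_band[:, 0], alpha=0.2)
    ax.axhline(power.Z_THRESHOLD, color="grey", ls="--", lw=0.8)
    if curve.n_star is not None:
        ax.axvline(curve.n_star, color="k", ls="--", lw=0.8)
    ax.set_title(setting)
    ax.set_xlabel("patients per arm")
np.atleast_1d(axes)[0].set_ylabel("z-score")
fig.tight_layout()
fig.savefig(OUT / "z_curves.png", dpi=120)
print(f"wrote {OUT}/sample_size.csv and z_curves.png")
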