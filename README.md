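# octsim

Virtual anti-VEGF trials of retinal thickness under home-OCT monitoring:
population PK/PD simulation, approximate nonlinear mixed-effects fitting,
bootstrap + Monte Carlo error propagation, and z-score sample-size analysis.

## The problem

Early trials in neovascular age-related macular degeneration (nAMD) read out
central subfield thickness (CST, µm) after intravitreal anti-VEGF
injections.  CST varies hugely between patients and is measured only at
sparse clinic visits, so detecting a between-drug difference takes many
patients.  Patient-operated home OCT devices can scan near-daily.  This
package asks, entirely in silico: *how many patients per arm does a
two-arm trial need to detect a ~40–50 µm CST difference at 95% confidence,
and how much does dense home monitoring plus PK/PD modeling reduce that
number compared with classical statistics on biweekly visits?*

## The model

Vitreous drug amount decays first order with drug-specific half-life
(`k_el = ln2 / t½`; aflibercept 9 d, ranibizumab 6.5 d); IVT boluses add
their dose instantaneously, so PK(t) is an analytic superposition of
exponentials.  CST follows an indirect-response model in which drug
stimulates CST loss through a Hill term:

    dCST/dt = k_in − k_out · [1 + E_max (PK+ε)^h / (EC50^h + (PK+ε)^h)] · CST
    k_out   = k_in / (CST_MIN + CST_DEL)
    E_max   = CST_DEL / CST_MIN

so untreated eyes settle at `CST_MAX = CST_MIN + CST_DEL` and treatment can
never push CST below `CST_MIN`.  Parameters are lognormal across patients,
`P_i = exp(θ + η_i)`, `η ~ N(0, Ω)` (diagonal; random effects on CST_DEL,
EC50, CST_MIN, CST_0 and PK_0), with additive residual noise σ = 5.5 µm.
Fitting maximises a Laplace (first-order-conditional) approximation to the
marginal likelihood, with EM updates for the population locations and
variances of the random effects; multistart waterfalls, profile-likelihood
CIs, and a prediction-corrected VPC check identifiability and adequacy.
`docs/methods.md` has the full account.

## Worked example

```python
import octsim

pop = octsim.trial_population()          # published estimates, CST_DEL mean 100 µm
design = octsim.default_trial_design()   # run-in wk 4/12, q8w to wk 36, endpoint wk 44
dataset = octsim.simulate_trial(pop, design, mode="home", seed=42)
for arm in dataset.arms:
    ep = dataset.endpoint_values(308.0, arm)
    print(f"{arm:12s} mean CST at week 44 = {ep.mean():6.1f} µm (SD {ep.std(ddof=1):5.1f})")
```

prints

```
aflibercept  mean CST at week 44 =  295.7 µm (SD  90.3)
trialdrug    mean CST at week 44 =  256.7 µm (SD  84.0)
```

i.e. a 39 µm treatment effect for this realization (the trial drug is
identical to aflibercept except for a 40 µm lower population-mean CST
floor; the simulated effect fluctuates by ±4–5 µm across seeds at 1000
patients/arm).  The numbered scripts under `analysis/` drive the full
study: `01` simulates the cohorts and quantifies the effect size, `02` fits
the model and runs the identifiability/adequacy diagnostics, `03`
propagates fitting uncertainty to the endpoint (bootstrap refits + Monte
Carlo), and `04` turns the standard-error curves into per-arm sample sizes
(tables and figures land under `results/`).  Pass `--quick` for smoke-scale
runs.

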