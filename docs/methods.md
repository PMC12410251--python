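# Methods

## The model

`octsim` simulates and estimates an indirect-response population PK/PD model
of central subfield thickness (CST, µm) in neovascular AMD eyes under
intravitreal (IVT) anti-VEGF bolus dosing.

**PK.** The vitreous drug amount PK (mg) follows first-order elimination,
`dPK/dt = -k_el · PK`, with a fixed drug-specific half-life
(`k_el = ln 2 / t_half`; 9 days for aflibercept, 6.5 days for ranibizumab).
Each IVT injection adds its full dose to the compartment instantaneously.
Because the equation is linear, PK(t) is evaluated analytically as a
superposition of decaying boluses — it is never integrated numerically.

**PD.** CST follows an indirect-response equation in which drug stimulates
the first-order loss rate through a Hill term:

    dCST/dt = k_in − k_out · [1 + E_max · (PK+ε)^h / (EC50^h + (PK+ε)^h)] · CST

with ε = 1e-8 retained verbatim from the model definition (numerically
irrelevant at therapeutic amounts; the Hill fraction is implemented in the
equivalent ratio form `1/(1+(EC50/(PK+ε))^h)`, which cannot underflow to
0/0).  The loss and stimulation parameters are derived from an
independence-oriented reparameterization,

    k_out = k_in / (CST_MIN + CST_DEL),   E_max = CST_DEL / CST_MIN,

so that the untreated steady state is `CST_MAX = CST_MIN + CST_DEL` and CST
can never be driven below `CST_MIN` (a patient whose sampled baseline CST_0
lies below the floor starts there and rises; ~15% of sampled patients do,
because CST_0 and CST_MIN are independent lognormals).

**Population structure.** Every structural parameter is lognormal across
patients: `P_i = exp(θ) · exp(η_i)`, `η ~ N(0, Ω)` with diagonal Ω
(variance convention).  Five parameters carry random effects — CST_DEL,
EC50 (one effect shared between drugs), CST_MIN, CST_0 and PK_0; K_IN and
the Hill coefficient H do not.  Observed CST adds residual noise
`Y = CST + e`, `e ~ N(0, σ²)`, σ = 5.5 µm.

**Default population** (log scale): CST_DEL 3.6, K_IN 4.0, EC50(afl) −1.7,
EC50(ran) −3.8, CST_MIN 5.42, CST_0 5.54, PK_0 −1.2, H 0.78; Ω = (1.02,
2.8, 0.033, 0.038, 4.5) for (CST_DEL, EC50, CST_MIN, CST_0, PK_0).  For
trial simulation the CST_DEL population mean is raised to 100 µm to
represent actively diseased study eyes.  We interpret "population mean" as
the arithmetic mean of the lognormal, `θ = ln(100) − Ω₁/2 = 4.095`: with
this convention the endpoint pool has SD ≈ 100 µm and the classical
baseline sample size lands at ≈49 patients per arm, internally consistent
with the z-score machinery; the median reading `θ = ln(100)` produces an
endpoint SD ≈ 145 µm and a baseline of ~100 patients per arm, inconsistent
with everything downstream.

## The virtual trial

Two arms, both starting with an aflibercept 2 mg run-in at weeks 4 and 12,
then randomized to q8w dosing (weeks 20, 28, 36) of either aflibercept or a
trial drug that is kinetically identical but lowers the population-mean CST
floor by 40 µm (226 → 186 µm).  The endpoint is CST at week 44 (day 308),
eight weeks after the last dose.  Sampling is either *home monitoring*
(five or six scans on random distinct days of each calendar week — a fair
coin decides 5 vs 6) or *on-site* (every 14 days).  The endpoint day is
always observed.  The simulated between-arm difference in mean endpoint CST
is ≈40–42 µm: the designed 40 µm floor shift plus small nonlinear terms
(single-realization noise at 1000 patients/arm is ±4–5 µm).

## Estimation

`fit_population` maximises a Laplace approximation to the marginal
likelihood (first-order conditional flavour): per patient the random-effect
vector is optimised to its conditional mode by a Levenberg–Marquardt
iteration on the penalised residual system, with the Gauss–Newton curvature
`J'J/σ² + Ω⁻¹` supplying the Laplace determinant; the outer problem runs
L-BFGS-B over the log fixed effects, log variances and log σ.

Numerical choices that matter:

- **Deterministic objective.** Every outer evaluation restarts the inner
  mode search from a fixed per-fit reference (refreshed at accepted outer
  iterates and optimizer restarts), so the objective is reproducible and
  line searches are not confused by warm-start jitter.  Without this,
  weakly-curved directions (parameters with large Ω, whose maximum-likelihood
  displacement changes the objective by less than the jitter) silently stay
  at their starting values and bootstrap spreads are underestimated.
- **Gradients.** Envelope-theorem gradients at the conditional modes: the
  structural components reuse the mode Jacobian columns, the variance and
  σ components are analytic through the curvature matrix.  The neglected
  logdet/mode-coupling terms bias the gradient by a few percent, which the
  restart policy (always at least two L-BFGS-B rounds, more while they make
  progress) absorbs.
- **EM updates for the flat directions.** Parameters with random effects
  are statistically flat: displacing a population location or variance by
  its full sampling SD changes the objective by less than the optimizer's
  numerical resolution, so quasi-Newton steps alone leave them near their
  starting values (and bootstrap spreads then fall *below* the sampling
  floor — a diagnostic we check).  Given the conditional modes these
  directions have closed-form maximisers — θ_k shifts by the mean mode,
  ω_k becomes the mean of (mode² + conditional variance), σ² absorbs the
  residual sum of squares plus its curvature correction — so each L-BFGS-B
  round is followed by EM sweeps (guarded by the objective) that settle
  them deterministically.
- **Tolerances.** Inner mode steps to 1e-8 (fresh-Jacobian verified); outer
  gradient tolerance 0.01 per patient (the objective is normalized per
  patient, which makes stopping invariant to dataset duplication); fitting-
  path integrator tolerances 1e-5 (trajectory error ~1e-3 µm, three orders
  below σ); simulation-path tolerances 1e-8.
- **Bounds and bail-outs.** Structural parameters ±3 log units around the
  start, log variances in [ln 1e-4, ln 50], σ in [0.5, 100] µm.  Points
  whose residuals exceed ~300σ per observation skip mode refinement (they
  are line-search probes far outside the plausible region).
- **Reproducibility floor.** The approximate likelihood surface has genuine
  nearby local optima (inner-mode switching between basins as θ varies), so
  independently started fits agree to ~1–10 OFV units while agreeing on the
  substantive estimates to ~0.01 log units.  Waterfall plots therefore show
  plateau structure at the method's resolution; multistart assertions in the
  tests use a 5–10-unit cluster width rather than the 1-unit plateau gap
  used for display.

Only single-drug datasets are fitted (each trial arm separately); the
absent drug's potency is excluded from estimation.  Profile likelihoods fix
one parameter on a grid, reoptimize the rest, smooth the OFV curve with a
tricube-weighted local quadratic (span 0.75) and read the 95% CI at
min + 3.84 (likelihood-ratio threshold).

## Error propagation and sample size

For a given per-arm size N, patients are drawn with replacement from a
1000-patient simulated pool (per arm) and the model is refitted; repeating
this yields an empirical distribution of the estimates, summarised by its
log-scale mean and covariance.  Monte Carlo propagation samples parameter
vectors from that multivariate normal and simulates, for each, the
**model-implied arm-mean endpoint**: the mean CST at day 308 over the IIV
distribution, evaluated with a set of standard-normal draws shared across
all parameter samples (so finite-draw noise cancels out of the spread; 64
draws by default, 4000 for the point estimate of the mean itself).  The SD
of these endpoint statistics is the model-based SE of the arm mean — the
same quantity the classical baseline estimates by bootstrapping the
arithmetic mean of simulated endpoint values.  Propagating the *typical*
(η = 0) trajectory instead (available as `statistic="typical"`) omits the
Ω-uncertainty contribution and gives materially smaller SEs; we use the
arm-mean statistic because the z-test compares arm means across settings.

The z-score is `z = Δ / sqrt(SE₁² + SE₂²)` with Δ the between-arm
difference in (model-implied or pool) mean endpoint CST, and the required
sample size n* is the smallest grid N with z ≥ 1.96.  Quantile ribbons
(2.5/97.5%) come from an outer bootstrap over the replicate estimate sets
(classical: over the pool), and their z-curves' crossings give an interval
around n*.

**Desk-scale choices.** The full design (200 bootstrap refits at every N on
a fine grid, two settings, two arms) is far beyond a workstation budget.
The packaged analysis and the test suite estimate the SE at two anchor
sizes (N = 24 and 48; 24 replicates in the analysis scripts, 16 in the test
suite) and carry the curve across the N grid by the asymptotic 1/sqrt(N)
law; anchor agreement with that law is itself checked.  At this scale each
SE carries 15-20% sampling error and n* inherits roughly twice that, so
sample-size outcomes are reported with their ribbon intervals rather than
as single integers, and ordering comparisons between the two monitoring
settings are at the edge of resolution.

## What the generator does and does not emulate

The synthetic cohorts reproduce the study conditions: lognormal IIV with
the estimated variances, additive 5.5 µm residual noise, randomized 5–6
scans/week home schedules, biweekly on-site visits, and the q8w dosing
scheme.  They do not model missed scans or dropout, scan-quality failures,
device-specific segmentation error, bilateral-eye correlation, or any
covariate structure — so passing tests demonstrate the statistical
machinery under the stated assumptions, not robustness of home-OCT trials
to real-world adherence and data-quality effects.

## Known limitations

- The estimator is a Laplace/FOCE-style approximation with numerical
  Jacobians, not NONMEM's FOCEI; objective values are comparable only to
  within the reproducibility floor above, and estimator-specific noise
  enters the bootstrap spreads (as it would for any estimator).
- Our fits extract more information from sparse biweekly data than the
  original workflow appears to (see the ledgered comparison): the on-site
  model-based route comes out *more* efficient than the classical baseline
  rather than equivalent to it, and the home-vs-on-site separation is
  smaller than reported.  The home-monitoring advantage direction is
  preserved.
- The simulated effect size is ≈40–42 µm where ≈48 µm is reported; the
  40 µm CST_MIN shift bounds what the model as specified can produce.
- Bootstrap ensembles use 16–24 replicates in packaged runs (vs. 200 at
  full scale); all sample-size numbers carry the corresponding Monte Carlo
  uncertainty.
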