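# Methods

`popkdesign` derives and evaluates blood-sampling schedules for population
pharmacokinetic (PK) studies of dihydroartemisinin (DHA) after oral
artesunate (AS). The pipeline is: structural PK models → population Fisher
information matrix (FIM) → constrained robust D-optimal design → sampling
windows → simulation–estimation evaluation.

## Structural and statistical model

DHA disposition is one-compartment with first-order elimination. Two
absorption forms are supported, each with an optional lag time t_lag:

* **Bateman** (first-order absorption, rate k_a distinct from the
  elimination rate k = CL/F ÷ V/F):
  C(t) = D·k_a / (V/F·(k_a − k)) · (e^{−k·τ} − e^{−k_a·τ}), τ = t − t_lag;
* **Dost** (the analytic limit k_a → k): C(t) = (D/(V/F))·k·τ·e^{−k·τ}.

The difference of exponentials is evaluated through
φ(x) = −expm1(−x)/x, so the Bateman form degrades gracefully into the Dost
form as k_a → k with no caller-side guard; far from that region the plain
two-exponential form is used (exact and overflow-free at extreme times).
All first derivatives with respect to the parameters are closed-form.

Between-subject variability (BSV) is log-normal,
p_i = θ·exp(η_i), η ~ MVN(0, Ω), entered as CV% with the first-order
convention ω = CV/100 (an exact log-normal inversion is available).
Residual error is combined: y = f·(1+ε₁) + ε₂.

Doses are mg/kg oral artesunate converted to DHA-equivalents by the molar
ratio 284.35/384.42 ≈ 0.7397 (configurable off); with a
proportional-dominant residual model the derived %RSEs are nearly invariant
to this choice.

### The residual-error reading

The adult reference analysis reports two residual-like quantities, 0.41 and
0.19, without units. Three readings were examined against the published
results:

* additive 0.19 **mg/L**: the FIM lower bound for RSE(k_a) becomes ~30%,
  above the *empirical* RSE of ~11% reported for the same design — an
  impossibility if that term had been in the data-generating model;
* proportional-only (0.41): information from proportional error alone is
  scale-free in time, so the D-optimum drifts to unrealistically late
  samples (~14 h, where concentrations are far below any assay limit);
* additive 0.19 on the **molar assay scale** (µmol/L ⇒ 0.054 mg/L; the
  reference assay reports molar concentrations): keeps the expected %RSEs
  within roughly a factor of two of the published expected-precision rows
  (e.g. RSE(k_a) 10.4 vs 5.44, RSE(V/F) 13.5 vs 10.2) *and* bounds the
  optimal schedule inside the first ~6 h.

The package default is the third reading — the only one consistent with
both published facts at once — with the additive floor applied to every
competing model as an assay property. It is configurable.

### Allometry and maturation

For children, CL/F scales as (W/W_ref)^0.75 and V/F as (W/W_ref)^1.0 with
W_ref = 50 kg (Asian adult cohort; a 70 kg preset mirrors the published
post-hoc check). Clearance carries an age maturation multiplier, default
exponential MF(age) = 1 − e^{−k_mat·age} with k_mat = 2 /year (≈86% mature
at 1 y, ≈98% at 2 y, consistent with rapid UGT-mediated DHA clearance
maturation); a Hill form is available. Design covariates use one
representative age per bracket (1, 6, 15.5 y) with weight 8.0 + 2.5·age kg.

## Population FIM and the robust D-criterion

For one subject the first-order marginal is E[y] ≈ f(θ),
Var[y] ≈ AΩAᵀ + R with A = ∂f/∂η at η = 0 and
R = diag(σ_add² + σ_prop²f²). The information matrix over the estimated
components ξ (free fixed effects; then BSV variances/covariances and σ² on
the variance scale) is

M[i,j] = dE_iᵀ V⁻¹ dE_j + ½·tr(V⁻¹ ∂V/∂ξ_i V⁻¹ ∂V/∂ξ_j).

The default is the full matrix including ∂V/∂θ and the cross-block
(`block_diagonal=True` drops them). ∂V/∂θ is assembled by central finite
differences (relative step 1e−5) over the analytic first derivatives; all
other blocks are closed-form. Group information is additive over subjects;
an observation before the absorption lag (f = 0) contributes no information
rather than making the design singular (a 1e−10 variance floor).

Fixed components (the adult lag 0.21 h; BSV(t_lag); the additive σ) are
excluded from the design-stage FIM: this component set reproduces the
published expected-precision rows most closely. Robustness over model
uncertainty uses the 3-point scheme: per structural variant, the central
estimates plus the all-lower and all-upper 95% CI parameter sets, with 95%
of the weight on the central members; the objective is the weighted sum of
logdet(FIM)/p over members (p the member's estimated-parameter count), so
efficiency comparisons are weighted geometric means.

## Design search

Coordinate exchange on a discrete time grid (1 min), restarted from 20
random feasible schedules plus a deterministic spread start by default;
candidate evaluations are vectorised over the entire grid, so a full
exchange pass is a handful of batched FIM evaluations per group. A coarse
(5 min) pass seeds a fine pass for the best starts. Ties break toward the
earliest grid time; the search is bit-reproducible given its seed. Group
schedules in multi-group designs are optimised jointly under the one
compound objective. An optional continuous polish (Nelder–Mead on a
log-gap transform that enforces ordering and minimum spacing by
construction) is off by default.

## Sampling windows

A window set assigns each optimal time an interval such that sampling
anywhere inside every window keeps at least 80% of the optimal design's
compound D-efficiency. Two stages, both using common random numbers:

1. per-time half-width caps by bisection, the other times held at their
   optima (caps are proportional to the local information sensitivity);
2. one global shrink factor bisected so that *joint* uniform sampling in
   all windows meets the floor.

The guarantee is worst-case over the sampled joint designs (the strict
minimum over 2 000–5 000 draws); a percentile criterion is available as a
softer contract. Worst-case was chosen after comparing both against the
published windows: a 5th-percentile contract yields windows uniformly much
wider than every published interval, while worst-case reproduces their
narrow widths — and it is the defensible promise to a field team.
Windows expand asymmetrically at the horizon ends and split neighbour
overlap at the midpoint; consecutive upper edges stay at least the minimum
spacing apart so the sequential in-window sampler is always feasible.

## Simulation–estimation

Virtual cohorts emulate the target populations: adult weights log-normal
(median 50 kg, CV 15%); child ages uniform within each bracket with weight
8.0 + 2.5·age kg ± 15% (truncated 3–70 kg); pregnant weights normal
(50 ± 6 kg, truncated positive). These distribution parameters are package
assumptions, not published values. Concentrations are simulated from the
full model; negative draws are floored at zero and flagged. Datasets
round-trip through NONMEM-style or tidy CSV.

The estimator maximises an approximate marginal likelihood over transformed
parameters (log fixed effects, log-Cholesky Ω blocks, log σ). Conditional
modes are found by a damped Gauss-Newton, batched over all subjects and all
finite-difference parameter variants at once, with a deterministic
multistart over η_tlag offsets: the mode problem is multimodal near the
absorption-lag kink, and taking the best basin keeps the outer objective a
continuous per-subject minimum of smooth branches. Two marginal
approximations are provided:

* **Laplace** (default): −2lnL_i = G(η̂) + n_i·ln2π + ln|Ω| + ln|H_G/2|
  with the exact joint Hessian H_G (finite differences of the analytic
  inner gradient);
* **FOCE-with-interaction style**: the classic linearised marginal about
  the modes with R evaluated at the individual prediction.

Laplace is the default because, against an exact quadrature/Monte-Carlo
likelihood oracle under the study's own conditions (ω_V/F ≈ 0.82,
proportional σ = 0.41, four samples per subject), the linearised objective
misjudges the marginal by tens of −2LL units and systematically prefers
CL/F inflated by ~20%, while Laplace tracks the oracle within a few units
and removes the bias. Both methods agree with each other and with the
oracle when variability is small.

The outer problem uses bounded L-BFGS-B on diagonally preconditioned
coordinates (a one-shot wide-step curvature probe sets the scaling), with
the whole forward-difference gradient obtained from a single batched inner
pass. Aborted line searches at mode-switch kinks trigger up to two
restarts; a restart that no longer improves the objective is accepted as
converged. Initial values are the true values inflated by +20% on the free
components. Empirical %RSE = 100·SD(estimates, n−1)/|median| over the
converged replicates only.

In the evaluation stage, the lag time is estimated while its BSV is fixed
at the simulated value (and the pregnant-women evaluation additionally
fixes BSV(k_a)), mirroring the reference procedure.

## Problem sizes and numerical choices

The packaged analyses use: design search with 6–8 random restarts on the
1-minute grid (coarse 5-minute pass first); window Monte Carlo with
1 200–2 000 joint draws; and a 30-replicate simulation–estimation study of
60 subjects (the replicate count is the package's chosen study size; the
empirical %RSEs are stable at this size to within a few points).
Tolerances: FIM symmetry 1e−12; exchange improvement threshold 1e−12;
window bisection to half the grid resolution; inner-mode gradient
tolerance 1e−8 relative; outer ftol 1e−9.

## What passing tests do and do not show

The synthetic generator reproduces the covariate structure, dosing rule,
log-normal BSV and combined residual error the study assumes. It does not
emulate assay censoring (an LLOQ flag exists but is off by default),
dropout, dose-time deviations, parent-drug kinetics, or model
misspecification beyond the competing-model set, so passing tests certify
the method's behaviour under the stated model, not field performance.

## Known limitations

* The exact FIM flavour of the original design software is unstated. Under
  the variants documented here, the derived adult optimum places a single
  sample in the absorption phase ({21 min, 1.8 h, 3.7 h, 5.1 h}) where the
  published schedule has two ({20 min, 35 min, 3.0 h, 6.2 h}); the first
  and last windows reproduce the published edges, the middle ones do not.
  Consequently the empirical precision of BSV(k_a) at our optimum is worse
  than the published bound.
* The pregnant-women efficiency surface is very flat after the last sample,
  so the derived last window extends later than the published 8.0 h edge.
* First-order FIM %RSEs for variance components are optimistic relative to
  the simulation-estimation results (as in the source study, where the
  empirical values ran consistently higher).
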