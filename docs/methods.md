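# Methods

## Structural model and units

All concentration computations rest on linear one-compartment kinetics
with first-order oral absorption and elimination, superposed over the
dose history.  Conventions fixed package-wide: doses in mg, times in
hours since the first tacrolimus dose, concentrations in ng/mL (µg/L).
The full model computes mg/L and multiplies by 1000; in the simplified
trough model that factor is absorbed into the composite parameter
`α = F·ka/(Vd·(ka−ke))`, which therefore carries (ng/mL) per mg of
remaining drug.  Units for `α` are a package convention — the quantity is
only ever used multiplied against a remaining amount in mg.

Dropping the absorption exponential is justified quantitatively, not just
asymptotically: over `ka ∈ [3, 6] h⁻¹`, `ke ∈ [0.02, 0.17] h⁻¹` and
trough gaps ≥ 10 h, the worst-case relative deviation between the two
models (with `α` set to the full composite) is below 10⁻¹⁰ — the error
term `e^{−(ka−ke)·gap}` is ≤ e⁻²⁸.  The approximation only matters if
the package were misused for non-trough times, which the module boundary
discourages.

`ke = 0` is accepted by the remaining-amount function (useful as a
degenerate test case: no elimination, amounts add), but rejected by the
structural parameter types.

One effective `ke` per prediction is assumed throughout; the sparse
trough-only data cannot support a time-varying elimination profile, and
the plausible band 0.017–0.17 h⁻¹ for adult kidney transplant recipients
is enforced architecturally where the model emits `ke`.

## Feature construction

Sequence samples: for a patient with `n` troughs, targets are troughs
2..n (the first trough is never a target anywhere in the package).  Step
`j` of a sample encodes history trough `j`: total dose since the previous
step (mg), the most recent single administration (mg), the observed
trough, time since the previous step, time since first dose, five labs
(haematocrit, albumin, ALT, AST, creatinine) imputed at the trough time,
and the static encoding (one-hot race, binary sex/smoking/alcohol/CYP3A
flags, five continuous anthropometrics) repeated at each step.  The exact
per-step layout is a package design choice; including the most recent
single administration alongside the aggregate gives the recurrent model
direct access to the dose scale that drives the trough level.

Lab values are linearly interpolated between adjacent observations and
carried at the edges.  When features are built for a prediction target,
only lab points observed strictly before the target time enter the
interpolation, so no sample sees post-target information — this is
enforced by a perturbation test (corrupting any post-target dose, trough
or lab leaves every feature unchanged).

Lag rows for the boosted model use the two most recent troughs before
the target (remaining drug amount, observed trough, empirical `α`, labs),
a missingness flag plus zero-fill when only one prior trough exists
(dropping those rows would discard the majority two-trough patients),
three time features and the static encoding.  Time after transplantation
is time after first dose plus a configurable offset (default 12 h;
therapy starts within 24 h of surgery).

Sub-LLOQ troughs (< 1 ng/mL) are censored at ingestion with a warning.
Normalization statistics (feature means/SDs) are fitted inside model
training from training patients only.

## Recurrent model

A single GRU layer (standard gating equations) with zero-padded,
masked batches: a masked step leaves the hidden state untouched, and the
output is read at the final valid step, so a sample's output is
invariant to whatever it is co-batched with (checked to 1e-12).  Two
parallel dense heads map the final hidden state to `α = softplus(·) + ε`
and `ke = 0.017 + 0.153·σ(·)`; the mapping into the band is a design
choice (the band itself is physiological).  `α` positivity is enforced
even though no upper constraint is placed on it — a non-positive `α` is
physically meaningless and breaks the trough equation.  Head biases are
initialized at population-typical values (α ≈ 1.7, ke ≈ 0.0578) so early
training starts from a sensible population model and gradient descent
learns individual deviations.

Training: Adam (lr 0.001), MSE on the predicted trough computed through
the trough equation over **all** doses up to the target time — doses
given after the last observed trough enter through the superposition
term only, which is what lets the model forecast under hypothetical
future regimens and hence recommend doses.  Up to 30 epochs, batch size
16, hidden size 32 (defaults; hidden size and batch are free parameters,
the rest is protocol).  No weight decay or schedule.  Gradients,
including the backward pass through the trough equation into both heads,
are analytic and verified against finite differences in the test suite.
The implementation is plain NumPy: the model is small (a few thousand
parameters), trains in seconds on one CPU, and an explicit backward pass
keeps the mechanism pathway transparent.

The purely data-driven ablation shares the trunk and passes the final
hidden state through one dense head (softplus, keeping predictions
non-negative) to predict the trough directly.  It carries no parameters
and no dose-linearity guarantee — that asymmetry is itself a tested
contrast: at frozen parameters the mechanism model scales exactly with a
uniform dose doubling, while the ablation's deviation (typically tens of
percent) is measured and reported without any exactness claim.

## Boosted model

Gradient boosting cannot learn `(α, ke)` by backpropagation, so `ke` is
fixed — population 0.0578 h⁻¹, or per-patient estimates from the MAP
forecaster (kept as an option; it performed worse in development, echoing
the weakness of individual estimates from sparse early data).  The
booster regresses the empirical `α` target (observed trough / remaining
amount at the target time) with rows weighted by the squared remaining
amount, which makes the α-scale squared error identical to the
trough-scale MSE the protocol minimizes.  Predicted `α` is floored at a
tiny positive value.  Hyperparameters (small grid over depth and number
of trees) are chosen by nested cross-validation: an inner patient-grouped
4-fold grid search inside each outer training set, winner refit on the
full outer-train, evaluated once on the outer test fold.  The ablation
drops the two mechanism-derived lags, adds the daily dose (total mg in
the 24 h before the target) and predicts the trough directly.

## Bayesian MAP baseline

The comparator is a *protocol* baseline: sequential a-posteriori
forecasting, where trough `n` is predicted from a MAP update on troughs
1..n−1 under a population prior — deliberately one-compartment, with
log-normal inter-individual variability on CL/F (ω = 0.35; volume fixed
by default) and a proportional residual error (σ = 0.20).  Defaults
(CL/F 21 L/h, V/F 300 L, ka 4.5 h⁻¹) put the population `ke` at
0.07 h⁻¹, inside the plausible band; all are configurable.  The MAP
objective includes the log(σ·f) Jacobian of the proportional error
model, which pulls the mode off the interpolating solution by O(σ²) —
visible in the self-consistency tests and intentional.  Optimization is
bounded L-BFGS-B on the log-deviations with three starts; non-finite
results fall back to the population-typical estimate with a warning.

## Dose recommendation

Candidate q12h doses on a 0.5 mg grid (0.5–15 mg) are appended to the
realized history over a forecast horizon (default 24 h, the next
scheduled TDM); the trough forecast at the horizon decides admissibility
against the closed target window [8, 12] ng/mL.  Forecasts within 0.1%
of a boundary count as attaining it — far below assay precision, and it
keeps boundary candidates (e.g. 4.0 mg at α = 2.0, ke = 0.0578, whose
steady-state forecast is 7.993 ng/mL) from being excluded by the
geometric-series residual.  The point recommendation minimizes the
distance to the window midpoint, ties resolved to the lower dose
(conservatism).  Candidates above 1.5× the prior dose are flagged as
excessive adjustments.  With mechanism parameters the forecast is
strictly increasing in dose, so the admissible set is a contiguous grid
run (asserted); the recommended *range* is the hull of that set.  The
same grid/protocol runs over the MAP forecaster for head-to-head
comparisons.

## Virtual-patient generator

The generator emulates the statistical structure the models assume:
q12h immediate-release dosing initiated at 0.075 mg/kg (0.5 mg
rounding), per-patient trough counts drawn from {2: .58, 3: .25, 4: .10,
5: .04, 6: .03} (mean ≈ 2.7, max 6), trough times immediately before a
scheduled administration with early-week density decaying over days 1–7,
and a TDM-feedback clinician emulator that rescales the dose by
target-midpoint / observed trough (clipped to [0.5×, 1.5×], re-rounded).
The emulator acts on the *noisy* observation, so its dosing is
deliberately imperfect — which is what allows model-guided dosing to
beat it in closed-loop comparisons.

Truth: `ka` 4.5 h⁻¹, `F` 0.25, typical `Vd` 125 L and CL 7.23 L/h
(population `ke` = 0.0578 h⁻¹, composite `α` ≈ 1.9 (ng/mL)/mg), residual
log-normal IIV ω_CL = 0.25 and ω_V = 0.25, a fast-metabolizer subgroup
(CL ×1.8, ~25% prevalence, race-correlated — a CYP3A5-expressor
surrogate), CYP3A inhibitor/inducer multipliers (×0.75 / ×1.4) and a mild
haematocrit effect on CL.  The residual ω_CL is the post-covariate value;
combined with the explicit covariate effects, total CL variability is
~35–40%, in line with published tacrolimus population analyses.
Observed troughs are the full-superposition value times (1 + ε),
ε ~ N(0, 0.15); sub-LLOQ values are censored.  Labs are bounded random
walks around cohort-typical baselines.  Defaults were calibrated once so
cohort summaries land in broad plausibility corridors (mean daily dose
8–16 mg, mean trough 5–14 ng/mL) and then frozen.

The external-shift configuration scales both the initial weight-based
dose and the feedback target window by 0.7, emulating a centre with a
lower-exposure protocol.  Scaling only the initial dose would be erased
within a day by the feedback loop; the joint shift reproduces the
lower-dose/lower-trough signature of a genuinely different centre
(synthetic external cohort: ~10 mg/day, ~7.6 ng/mL vs ~14 mg/day,
~10.8 ng/mL internally) and makes the shift comparison a real
extrapolation test.  Under it the mechanism-informed models beat their
ablations decisively in held-out MSE, while internal cross-validation
shows near-parity — the same qualitative pattern the architecture is
designed to produce.

What the generator does **not** emulate: intra-patient parameter
drift over the week (physiological recovery), assay-specific error
structure, non-adherence, drug–drug interaction kinetics, enterohepatic
recirculation, or correlation between labs and time-varying clearance
beyond the baseline haematocrit effect.  Passing tests on this generator
therefore demonstrate architectural correctness and protocol validity,
not clinical performance.

## Known limitations: parameter identifiability

Most virtual (and real) patients carry only one history trough when a
prediction is due.  A single noisy trough cannot jointly identify `α`
and `ke`; any estimator must attribute the observed level to some mix of
exposure (α) and elimination (ke), informed only by covariates.  With
realistic unexplained `ke` variability (residual IIV plus the
imperfectly race-predicted fast-metabolizer effect), the misattribution
contaminates individual `α` estimates by a factor `e^{−Δke·t}` with `t`
around 18 h.  Quantitatively, on the 500-patient recovery cohort, an
empirical-α estimator given the *true* individual `ke` reaches held-out
MSE ≈ 2.2× the irreducible noise floor and rank-correlates with true
F/Vd at ρ ≈ 0.86; the same estimator at the population `ke` reaches
≈ 2.5× with ρ ≈ −0.1, and a MAP estimator given the oracle
covariate-conditional prior ≈ 2.5× with ρ ≈ 0.33.  The trained
mechanism GRU lands near 2.9–3.4× with ρ ≈ −0.1: close to what is
achievable at the population-`ke` information level, and the acceptance
script reports these measured values as they are.  Tightening them would
require either richer sampling (more troughs per patient) or an
unrealistically homogeneous elimination rate in the generator; the
package reports the honest numbers instead.  The controlled recovery
experiment — noise-free patients on an `α` grid at one shared `ke` —
does confirm the architecture recovers `α` cleanly (ρ ≥ 0.9) whenever it
is identifiable.

## Numerical choices

Plain double-precision exponentials everywhere (exponents are bounded by
~30 in magnitude); no log-sum-exp needed.  Metric suite: MPE is signed
with positive = overprediction; R² is undefined (reported missing) for a
single pair; all six metrics are verified against an independent
loop-based recomputation to 1e-10 relative.  Fold assignment is
patient-level, stratified on trough-count bins {2, 3, ≥4}, dealt
round-robin after a seeded shuffle; both fold-averaged and pooled metrics
are emitted (pooled is the deterministic aggregation used for
comparisons).  Permutation importance uses 10 seeded repeats over pooled
real time-steps; gain importance normalizes booster gains to percentage
shares.
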