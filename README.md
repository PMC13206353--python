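# tacdose

Mechanism-informed machine learning for tacrolimus trough forecasting and
individualized dose adjustment in the early post-kidney-transplant period.

Tacrolimus has a narrow therapeutic index and large between-patient
pharmacokinetic variability; in the first week after transplantation fewer
than 40% of troughs land in the therapeutic window under conventional
TDM-guided dosing.  `tacdose` implements forecasting models that do not
predict the trough directly but instead estimate each patient's
pharmacokinetic parameters and push them through an explicit linear-PK
superposition equation — which makes predictions dose-linear,
interpretable, and invertible into dose recommendations.

## The model

Under linear one-compartment kinetics with first-order oral absorption
(rate `ka`) and elimination (rate `ke`), the concentration after multiple
doses `D_i` at times `t_i` is

    C(t) = Σ_i  F·ka / (Vd·(ka−ke)) · D_i · (e^{−ke(t−t_i)} − e^{−ka(t−t_i)})

Immediate-release tacrolimus is absorbed within 0.5–2 h while troughs are
drawn ~12 h post-dose, so the absorption exponential is negligible at
trough times and the equation collapses to

    C_trough(t) = α · Σ_i D_i · e^{−ke(t−t_i)} ,    α = F·ka/(Vd·(ka−ke)) ≈ F/Vd

where `Σ_i D_i e^{−ke(t−t_i)}` is the **remaining drug amount** (mg) and
`α` is a composite exposure parameter in (ng/mL)/mg.  Two learners emit
these parameters from longitudinal dosing/TDM/lab/covariate histories:

* **Mechanism-informed GRU** — a single masked GRU layer over per-trough
  feature sequences; the final hidden state feeds two parallel dense
  heads for `α` (softplus, positive) and `ke` (logistic-squashed into the
  physiological 0.017–0.17 h⁻¹ band); trained end-to-end by MSE on the
  trough computed through the equation above (Adam, lr 0.001, ≤30
  epochs).  Implemented in NumPy with analytic gradients.
* **Mechanism-informed XGBoost** — `ke` fixed (population 0.0578 h⁻¹ or
  a per-patient Bayesian estimate), a booster predicts `α` from lag
  features of the two most recent troughs (remaining amount, observed
  trough, empirical `α` = trough / remaining amount, labs, time and
  static features), tuned by nested (inner 4-fold, patient-grouped) CV.

Both have purely data-driven ablations (direct trough prediction), and a
sequential a-posteriori Bayesian (MAP) forecaster over a one-compartment
population prior serves as the PopPK-style baseline.  A virtual-patient
simulator with known ground truth (q12h dosing initiated at 0.075 mg/kg,
sparse ~2.7 troughs/patient, TDM-feedback dose adjustment, covariate-
dependent clearance, proportional error) makes the whole pipeline
testable at desk scale.  Dose recommendation inverts the forecast over a
0.5 mg grid to hit a target window (default 8–12 ng/mL), flagging
adjustments above 1.5× the prior dose.

## Worked example

```bash
tacdose simulate --out cohort/ --n-patients 100 --seed 7
tacdose evaluate --data cohort/ --model xgb_mech --folds 5 --seed 7 --out run/
```

prints the pooled cross-validated metrics (your numbers will match these
exactly at the same seed):

```json
{"mse": 9.78, "mae": 2.44, "r2": 0.109, "mpe": 8.39, "rmsrpe": 33.9,
 "p10": 24.9, "p20": 51.4, "p30": 68.4, "n": 177}
```

i.e. on this small 100-patient cohort the mechanism-informed booster
predicts the next trough with a mean absolute error of ~2.4 ng/mL, ~8%
mean overprediction bias, and 68% of predictions within ±30% of the
observed value (R² is low at this cohort size; it rises to ~0.38 at 500
patients, the scale the acceptance script uses).  Recommending a dose for
one patient with frozen parameters α = 2.0 (ng/mL)/mg, ke = 0.0578 h⁻¹:

```bash
tacdose recommend --data cohort/ --patient-id P00000 --alpha 2.0 --ke 0.0578
```

returns the admissible q12h dose set (here 4.0–6.0 mg: at steady state
the trough is ≈ 2.0 × 0.999 × dose, so the 8–12 ng/mL window maps to
that grid run), the point recommendation nearest the 10 ng/mL midpoint,
the per-candidate forecasts, and any excessive-change flags.

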