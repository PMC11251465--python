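# ea-trial-sim

Simulation-aided design of randomized controlled trials (RCTs) for
EEG-guided anti-seizure treatment in aneurysmal subarachnoid hemorrhage
(aSAH).

Patients with acute brain injury frequently show epileptiform activity (EA)
on continuous EEG, and higher EA burden predicts worse functional outcome —
yet trials of anti-seizure treatment keep failing at the design stage, with
sample sizes picked from misspecified nulls. This package is for trialists
and biostatisticians who want to ground a power analysis in observational
data: it chains a mechanistic drug-response model, a doubly robust outcome
model, and a Monte-Carlo trial engine into power curves and minimal per-arm
sample sizes for candidate levetiracetam and propofol regimens.

## The model

**Exposure.** EA burden is the fraction of EA-positive 2-second segments per
non-overlapping 10-minute window; the scalar exposure is
E_max = max over 6-h sliding windows of the mean burden.

**Drug response.** One-compartment kinetics with first-order elimination
give concentration C(t) in closed form for any bolus/infusion schedule
(superposition). Burden is suppressed by a Hill function,

    S(C) = C^h / (ED50^h + C^h),     b(t) = b0 e^{-λt} (1 − S(C(t))),

with per-patient (k_e, ED50, h, b0, λ) estimated by minimizing trajectory
MSE (V fixed per drug; concentrations are never observed).

**Outcome.** Discharge modified Rankin Scale, dichotomized good (0–3) /
poor (4–6), is modeled with double machine learning in the partially linear
model Y = θ′T + g(X) + ε, T = (E_max, mean drug concentration), with
gradient-boosted, cross-fitted nuisances; a boosted classifier g_hat
supplies P(poor | T, X) for trial simulation.

**Trials.** Virtual patients are bootstrap draws from the cohort; each arm's
regimen (e.g. levetiracetam 15/7/3 mg/kg q8h or placebo, all on top of the
patient's background standard care) is pushed through the patient's own
PK/PD model, outcomes are Bernoulli draws from g_hat, and arms are compared
with a two-sided Welch t-test. Power is the rejection fraction over
replicate trials; the minimal per-arm n meeting a target power is found by
doubling-then-bisection with a Monte-Carlo-error guard.

Because the study's real cohort is not bundled, the package ships a
synthetic-cohort generator with the same covariate margins (48 patients,
median age 61, 79% female, two-thirds treated, median 183 h of EEG) and a
fully known ground truth, so every stage — burden, PK/PD fitting, effect
estimation, trial simulation — is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the pipeline on the synthetic
cohort and write their tables under `results/`:

```
$ python analysis/01_generate_cohort.py
cohort: 48 patients (seed 20240612)
  age median (Q1-Q3): 68 (57-85)
  female: 79.2%
  EEG duration median: 186 h
  treated: 75.0% (propofol in 22.9%)
  poor outcome (mRS 4-6): 50.0%
  E_max median: 0.337

$ python analysis/02_fit_pkpd.py
fitted 96 (patient, drug) pairs; 47 with identifiable drug effect
  trajectory MSE median: 5.42e-04
  levetiracetam ED50 median relative error vs truth: 2.9%

$ python analysis/04_power_analysis.py
levetiracetam:mid_vs_placebo: did not reach 80% power by n=5000/arm (power 0.35)
...
```

Reading the output: one synthetic 48-patient cohort is a single draw, so its
margins wobble around the configured targets (age median 68 here vs 61 in
expectation). The PK/PD fitter recovers the generating ED50 to a few percent
from dosing and burden alone. At this cohort size the fitted outcome
predictor carries small arm contrasts, so the simulated trials honestly
report that no dose contrast reaches 80% power within 5000 patients per arm
under these synthetic conditions — the sample-size search returns an explicit
"not reached" sentinel rather than extrapolating. Scripts `03` and `05`
report the doubly robust effect estimates and the ED50 potency sweep.

The engine is validated against analytic theory where theory exists: e.g.
`two_proportion_n(0.60, 0.45)` = 173 per group, and the Monte-Carlo search
on a degenerate design with those fixed outcome probabilities lands within
15% of it.

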