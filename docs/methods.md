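# Methods

This package implements a simulation-aided design pipeline for randomized
trials of EEG-guided anti-seizure treatment in aneurysmal subarachnoid
hemorrhage (aSAH). The pipeline has four stages: quantify epileptiform-activity
(EA) burden from labelled continuous EEG; estimate per-patient
pharmacokinetic/pharmacodynamic (PK/PD) response of EA burden to levetiracetam
and propofol; estimate the effect of EA burden and drug exposure on
dichotomized discharge outcome with a doubly robust machine-learning model;
and run Monte-Carlo simulated randomized trials over a virtual cohort to
obtain power curves and minimal per-arm sample sizes.

## EA burden and E_max

EEG is labelled as 0/1 EA per 2-second segment (seizures, LPDs, GPDs and LRDA
pooled; the labelling itself is an input, not part of this package). Burden is
the fraction of positive segments in consecutive, non-overlapping 10-minute
windows (300 segments each); trailing partial windows are dropped rather than
padded, since a fraction over an incomplete window is not comparable. The
exposure summary is `E_max`, the maximum mean burden over 6-hour sliding
windows of the burden series, sliding by one 10-minute bin — the finest stride
the burden resolution supports. Records shorter than 6 h degenerate to a
single whole-record window (the global mean), which keeps the statistic
defined and in [0, 1]. Missing or artifact segments are not modelled; labels
are assumed dense.

## Pharmacokinetics

Serum concentration follows a one-compartment model with first-order
elimination, dC/dt = input(t)/V − k_e·C. Because the ODE is linear, arbitrary
bolus/infusion schedules are solved in closed form by superposition; the
implementation is validated against independent numeric ODE integration to
0.1% on random schedules. Concurrent infusions of the same drug superpose
(rates add), which arises whenever a randomized study infusion is layered on
top of a background standard-care infusion. IV boluses are treated as
instantaneous. The distribution volume V is fixed per drug at literature
values (levetiracetam 0.6 L/kg, propofol 4.0 L/kg) because D/V and ED50 are
jointly unidentifiable from burden data alone — no plasma concentrations enter
the model. Elimination defaults come from literature half-lives (levetiracetam
t½ ≈ 7 h, propofol effective t½ ≈ 1 h) and k_e is estimated within one decade
of the default.

## Pharmacodynamics

Treatment suppresses burden through a sigmoidal (Hill) function
S(C) = C^h / (ED50^h + C^h), where ED50 is the concentration that halves the
EA burden in a 10-minute window and h sets the steepness of effect onset. The
untreated baseline is b0·exp(−λ·t): an exponentially decaying baseline
captures the waning of EA over days of monitoring with two parameters
(a constant baseline is the λ = 0 special case). Treatment acts
multiplicatively, b(t) = baseline(t)·(1 − S(C(t))), consistent with ED50
defined as a 50% reduction from the untreated level; multiple concurrent
drugs multiply their surviving fractions, each with its own ED50 and Hill
coefficient. These functional forms are the package's reconstruction of a
standard inhibitory E_max model; they are deliberately minimal and every
piece is configurable.

## Per-patient parameter estimation

(k_e, ED50, h, b0, λ) are estimated per patient and drug by minimizing the
mean squared error between the simulated and observed burden trajectory on
the 10-minute grid. The objective is optimized in log space for the positive
parameters by bound-constrained Nelder–Mead from 8 Latin-hypercube starts
plus the literature default, followed by a restart polish from the incumbent
(a fresh simplex escapes collapsed geometry); ties break by lower MSE, then
lower ED50. Tolerances are 1e-8 (simplex) with ≤2000 evaluations per start.
Records with no dose events identify only (b0, λ); ED50 and h are then
flagged non-identifiable rather than silently returned. Fits terminating
within 1% of a parameter bound carry a warning flag. On noise-free
self-generated trajectories the optimizer recovers parameters to well under
1% relative error; under the Bernoulli observation model (below), median ED50
error over 50 replicates of a 10-day q8h regimen is about 1–3%, frozen in the
tests as a ≤25% regression bound.

## Outcome model

Discharge modified Rankin Scale is dichotomized good (0–3) / poor (4–6). The
effect of the exposure vector T = (E_max, mean drug concentration during
treatment) on P(poor) is estimated with double/debiased machine learning in
the partially linear model Y = θ′T + g(X) + ε: gradient-boosted trees
(200 trees, depth 3, learning rate 0.05 — fixed for small-n stability) learn
E[Y|X] and E[T_j|X] with 5-fold cross-fitting, and θ is the residual-on-
residual regression with heteroskedasticity-robust standard errors. Squared
loss gives θ a linear-probability reading (percentage points of poor-outcome
risk per unit exposure). Confounders X are the baseline covariates (age, sex,
Hunt–Hess, Fisher, time-to-EEG, EEG duration, weight) plus the per-patient
PK/PD parameters, which encode treatment-response heterogeneity and the
indication for treatment. Constant exposure columns are flagged
non-identifiable; degenerate outcomes (all one class) are an error.

For the trial engine, a separate gradient-boosted classifier `g_hat` predicts
P(poor | E_max, mean concentration, X), clipped to [0.01, 0.99] before
Bernoulli sampling. `g_hat`'s feature set includes the PK/PD parameters: in
the generator (and plausibly in real data) treatment leans toward
high-burden patients, and omitting the burden-propensity parameters from
`g_hat` lets that confounding-by-indication leak into simulated arm
contrasts, up to inverting the apparent direction of drug benefit. `g_hat`
is not constrained monotone in E_max; at small n its E_max dependence is
noisy, which dilutes simulated arm contrasts (see Limitations).

## Simulated trials

A virtual patient is a uniform draw with replacement from the cohort,
carrying covariates, fitted PK/PD parameters and the observed background
standard-care dosing. Each arm's regimen (levetiracetam 15/7/3 mg/kg boluses
every 8 h, propofol 1/0.5/0.25 mg/kg/h infusions, or placebo) is added on top
of the background dosing — "placebo with standard care" retains the observed
treatment. Treatment runs from the first EA measurement (t = 0) for
min(EEG duration, 240 h), matching a 10-day monitoring protocol. The
resulting deterministic trajectory yields (E_max, mean concentration), a
poor-outcome probability from `g_hat`, and a Bernoulli outcome; a designated
arm pair is compared with a two-sided Welch t-test on the 0/1 outcomes (a
t-test rather than a chi-square, matching the design being emulated). Because
a given cohort patient's trajectory under a fixed regimen is deterministic,
per-(patient, arm) probabilities are precomputed once and replicate trials
reduce to index resampling and Bernoulli draws, making thousands of
replicates cheap.

Power at per-arm n is the rejection fraction over R replicate trials
(default R = 500; binomial Monte-Carlo SE reported). The minimal n for a
target power (default 80%) is searched on a doubling grid then bisection; a
size counts as sufficient only when power − 2·SE ≥ target, guarding the
decision against Monte-Carlo error (a flag disables the guard). Non-attainment
at n_max returns an explicit sentinel with the power achieved there. The
engine also provides the closed-form normal-approximation two-proportion
sample size as an analytic cross-check, and an ED50 sweep that rescales every
patient's ED50 at fixed n to locate the drug potency detectable with the
target power. All engine outputs are per-arm; report layers multiply by the
number of arms for totals.

## Synthetic cohort generator

The generator emulates the observational cohort the pipeline is designed for:
48 patients by default; age log-normal matched to median 61 (IQR 51–74);
79% female; Hunt–Hess probabilities (.125, .125, .291, .313, .146); Fisher
(0, .042, .708, .250); time-to-EEG discrete around a median of 24 h; EEG
duration log-normal matched to median 183 h (IQR 139–230), floored at 24 h;
weight ~ N(75, 15²) truncated to [40, 150] kg (weight only converts per-kg
doses and cancels elsewhere). Two thirds are treated, with assignment leaning
toward high-baseline-burden patients (confounding by indication, strength
0.3 on the b0 scale) while preserving the marginal treated fraction. Treated
patients receive background levetiracetam 7 mg/kg at jittered ~q8h intervals;
a quarter of them additionally receive a 48-h propofol infusion at
0.5 mg/kg/h.

Per-patient PK/PD parameters are log-normal around literature medians
(levetiracetam ED50 10 mg/L, propofol ED50 1 mg/L, Hill 2, CVs 0.3–0.5);
baseline burden b0 ~ Beta(2.5, 3.5) and decay λ log-normal with median
0.004/h. Observed burden per 10-minute window is Binomial(300, b)/300 —
exactly the law of labelling each 2-second segment independently — so label
series never need materializing at scale. Discharge outcome is drawn from a
linear-probability model P(poor) = clip(0.35 + 0.135·E_max − 0.005·mean_conc
+ small covariate terms, 0.01, 0.99), using the observed E_max so the
generating coefficient is the estimand of the analysis; mRS within the
good/poor class is drawn from fixed sub-distributions. All latent parameters
and probabilities are exported in a ground-truth table keyed by patient id.

What the generator does not emulate: EEG waveforms and labelling error,
artifact gaps, dose titration in response to EA, non-stationary baselines
beyond exponential decay, and long-term outcomes. Passing recovery tests on
this generator therefore demonstrates the estimators are consistent under
the package's own assumptions, not that those assumptions hold in real
cohorts.

## Numerical and design choices

- All times are hours from the first EA measurement; intervals are half-open;
  everything lives on the 10-minute grid that matches burden resolution.
- Every stochastic operation takes an explicit seed; nested streams derive
  from `numpy.random.SeedSequence` spawning, so reruns are bit-identical and
  no global RNG state is touched.
- Degenerate Welch comparisons (both arms zero-variance) return p = 1 when
  means agree and p = 0 otherwise.
- Propofol's middle arm is 0.5 mg/kg/h, following the enumerated arm list
  for that drug.
- The DML variant is partialling-out (residual-on-residual); an
  augmented/interactive variant was considered and left out of scope.
- Test problem sizes (e.g. 50-seed recovery studies at n = 1000, 2000-replicate
  trial batteries) were chosen to keep the default suite comfortably under a
  half hour on one core while leaving Monte-Carlo bands at least ~3 SE wide.

## Limitations

- E_max is weakly identified given the confounders: most of its variance is
  explained by b0 and treatment status, so θ_emax carries a standard error
  near 0.2 even at n = 1000 generated patients. End-to-end recovery tests
  therefore assert unbiasedness across seeds rather than tight per-run error.
- At n = 48 the gradient-boosted `g_hat` largely memorizes patients through
  their covariates, leaving small simulated arm contrasts; under the default
  synthetic conditions no dose contrast reaches 80% power by 5000 per arm.
  Conclusions about real trial feasibility require the real cohort's fitted
  models, not the synthetic stand-in.
- The ED50 sweep changes potency but not concentration, so any direct
  concentration dependence learned by `g_hat` (side-effect-like pathways or
  small-sample noise) keeps arm contrasts alive even for an ineffective drug;
  the sweep's null limit is exact only when outcome depends on drug solely
  through burden.
- One-compartment PK without plasma-level assimilation; no drug interactions
  beyond multiplicative burden suppression; no dose titration policies.
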