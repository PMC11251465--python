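"""Monte-Carlo simulated randomized trials, power curves and sample sizes.

A simulated trial draws virtual patients by resampling the cohort with
replacement (covariates and fitted PK/PD parameters travel together),
randomizes each into a treatment arm, simulates the EA-burden trajectory
under the assigned regimen *added on top of* the patient's background
standard-care dosing, converts the resulting exposure into a poor-outcome
probability with the fitted outcome model, draws the dichotomized
discharge mRS, and compares a designated pair of arms with a two-sided
Welch t-test on the 0/1 outcomes.  Power at a given per-arm n is the
fraction of replicate trials rejecting at level alpha; the minimal n for
a target power is found on a doubling-then-bisection grid.

Because a cohort patient's trajectory under a fixed regimen is
deterministic, each (patient, arm) poor-outcome probability is
precomputed once and trial replication reduces to index resampling and
Bernoulli draws, which keeps thousands of replicates cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from ea_trial_sim.ea_burden import BurdenSeries, compute_emax
from ea_trial_sim.outcome_dml import (
    ExposureSummary,
    OutcomeModel,
    predict_outcome_batch,
)
from ea_trial_sim.pkpd import (
    ConcentrationProfile,
    DoseEvent,
    concentration_profile,
    events_for_drug,
    rescale_ed50,
    simulate_burden_multidrug,
    time_grid,
)
from ea_trial_sim.records import PatientRecord

#: cEEG monitoring (and hence simulated treatment) is capped at 10 days
MAX_TREATMENT_HOURS = 240.0

REGIMEN_KINDS = ("bolus_q", "infusion", "placebo")


@dataclass(frozen=True)
class Regimen:
    """One treatment arm's dosing rule.

    ``dose`` is mg/kg per administration for ``bolus_q`` (given every
    ``interval`` hours) and mg/kg/h for ``infusion``; placebo arms add no
    study drug (standard care continues regardless).
    """

    drug: str
    kind: str
    dose: float = 0.0
    interval: float = 8.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in REGIMEN_KINDS:
            raise ValueError(f"kind must be one of {REGIMEN_KINDS}")
        if self.kind != "placebo" and self.dose <= 0:
            raise ValueError("dose must be > 0 unless placebo")
        if self.kind == "bolus_q" and self.interval <= 0:
            raise ValueError("bolus interval must be > 0")
        if self.label is None:
            if self.kind == "placebo":
                name = "placebo"
            elif self.kind == "bolus_q":
                name = f"{self.drug} {self.dose:g} mg/kg q{self.interval:g}h"
            else:
                name = f"{self.drug} {self.dose:g} mg/kg/h"
            object.__setattr__(self, "label", name)


def standard_arms(drug: str) -> list[Regimen]:
    """The four per-drug arms: three active doses plus placebo."""
    if drug == "levetiracetam":
        doses = (15.0, 7.0, 3.0)
        return [Regimen(drug, "bolus_q", d) for d in doses] + [Regimen(drug, "placebo")]
    if drug == "propofol":
        rates = (1.0, 0.5, 0.25)
        return [Regimen(drug, "infusion", r) for r in rates] + [Regimen(drug, "placebo")]
    raise ValueError(f"no standard arms defined for {drug!r}")


@dataclass(frozen=True)
class TrialDesign:
    """Arms, per-arm size, test level and the contrasted arm pair."""

    arms: tuple[Regimen, ...]
    n_per_arm: int
    alpha: float = 0.05
    contrast: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise ValueError("need at least two arms")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        i, j = self.contrast
        if not (0 <= i < len(self.arms) and 0 <= j < len(self.arms) and i != j):
            raise ValueError("contrast must index two distinct arms")
        object.__setattr__(self, "arms", tuple(self.arms))


@dataclass(frozen=True)
class TrialResult:
    proportions: tuple[float, ...]  # poor-outcome fraction per arm
    statistic: float
    p_value: float
    n_per_arm: int
    seed: int


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    se: float  # binomial Monte-Carlo standard error
    replicates: int


@dataclass(frozen=True)
class PowerCurve:
    n_grid: tuple[int, ...]
    power: tuple[float, ...]
    se: tuple[float, ...]
    replicates: int
    seed: int


@dataclass(frozen=True)
class SampleSizeResult:
    """Minimal per-arm n achieving the target power, or a sentinel."""

    reached: bool
    n_per_arm: int | None
    power_at_n: float
    target_power: float
    n_max: int
    seed: int


@dataclass(frozen=True)
class Ed50SweepResult:
    multipliers: tuple[float, ...]
    power: tuple[float, ...]
    se: tuple[float, ...]
    crossing: float | None  # interpolated multiplier where power falls to target
    target_power: float


# ---------------------------------------------------------------------------
# virtual patients and regimens


def sample_virtual_patient(
    cohort: Sequence[PatientRecord], rng: np.random.Generator
) -> PatientRecord:
    """Uniform draw with replacement from the cohort."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    return cohort[int(rng.integers(len(cohort)))]


def regimen_events(regimen: Regimen, duration_h: float) -> list[DoseEvent]:
    """Expand a regimen into dose events on [0, duration)."""
    if regimen.kind == "placebo":
        return []
    if regimen.kind == "bolus_q":
        times = np.arange(0.0, duration_h, regimen.interval)
        return [
            DoseEvent(regimen.drug, float(t), "bolus", regimen.dose) for t in times
        ]
    return [
        DoseEvent(regimen.drug, 0.0, "infusion_start", regimen.dose),
        DoseEvent(regimen.drug, duration_h, "infusion_stop"),
    ]


def apply_regimen(
    patient: PatientRecord, regimen: Regimen
) -> tuple[ExposureSummary, BurdenSeries]:
    """Exposure summary and burden trajectory under a randomized arm.

    The randomized regimen is added on top of the patient's background
    standard-care dosing.  Treatment runs from t = 0 for
    min(EEG duration, 240 h).  ``mean_conc`` averages the summed drug
    concentration from the first dose event to the end of treatment
    (zero when no drug is ever given).
    """
    if not patient.pkpd:
        raise ValueError(f"patient {patient.patient_id} has no PK/PD parameters")
    duration = min(patient.covariates.eeg_duration, MAX_TREATMENT_HOURS)
    times = time_grid(duration)
    events = list(patient.doses) + regimen_events(regimen, duration)
    drugs = sorted({ev.drug for ev in events})
    profiles: list[tuple] = []
    total_conc = np.zeros_like(times)
    for drug in drugs:
        if drug not in patient.pkpd:
            raise ValueError(
                f"patient {patient.patient_id} lacks PK/PD parameters for {drug!r}"
            )
        pk, pd_params = patient.pkpd[drug]
        conc = concentration_profile(events_for_drug(events, drug), pk, times)
        profiles.append((pd_params, conc))
        total_conc += conc.values
    burden = simulate_burden_multidrug(patient.baseline_pd(), profiles, times)
    if events:
        t_first = min(ev.time for ev in events)
        in_treatment = times >= t_first
        mean_conc = float(total_conc[in_treatment].mean()) if in_treatment.any() else 0.0
    else:
        mean_conc = 0.0
    return ExposureSummary(e_max=compute_emax(burden), mean_conc=mean_conc), burden


def arm_probability_table(
    cohort: Sequence[PatientRecord],
    model: OutcomeModel,
    arms: Sequence[Regimen],
) -> np.ndarray:
    """P(poor outcome) for every (cohort patient, arm) pair.

    This is the deterministic kernel of the trial engine: replicated
    trials only resample rows of this table.
    """
    table = np.empty((len(cohort), len(arms)))
    for j, arm in enumerate(arms):
        exposures = []
        for patient in cohort:
            exposure, _ = apply_regimen(patient, arm)
            exposures.append(exposure)
        table[:, j] = predict_outcome_batch(model, exposures, cohort)
    return table


# ---------------------------------------------------------------------------
# hypothesis testing


def welch_ttest_binary(
    y_a: np.ndarray, y_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Welch t-test along the last axis.

    Accepts (..., n) arrays of 0/1 outcomes; degenerate (zero-variance)
    comparisons give p = 1 for equal means and p = 0 otherwise.
    """
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    na, nb = y_a.shape[-1], y_b.shape[-1]
    ma, mb = y_a.mean(-1), y_b.mean(-1)
    va, vb = y_a.var(-1, ddof=1), y_b.var(-1, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = denom == 0
    with np.errstate(invalid="ignore"):
        p = np.where(zero, np.where(ma == mb, 1.0, 0.0), p)
        t = np.where(zero, np.where(ma == mb, 0.0, np.inf * np.sign(ma - mb)), t)
    return t, p


def _replicate_pvalues(
    table: np.ndarray,
    contrast: tuple[int, int],
    n_per_arm: int,
    replicates: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """p-values and per-arm-pair proportions for replicated two-arm trials."""
    n_patients = table.shape[0]
    i, j = contrast
    idx_a = rng.integers(n_patients, size=(replicates, n_per_arm))
    idx_b = rng.integers(n_patients, size=(replicates, n_per_arm))
    y_a = (rng.random((replicates, n_per_arm)) < table[idx_a, i]).astype(float)
    y_b = (rng.random((replicates, n_per_arm)) < table[idx_b, j]).astype(float)
    _, p = welch_ttest_binary(y_a, y_b)
    return p, np.stack([y_a.mean(-1), y_b.mean(-1)], axis=-1)


def simulate_trial(
    cohort: Sequence[PatientRecord],
    model: OutcomeModel,
    design: TrialDesign,
    rng_seed: int,
    *,
    prob_table: np.ndarray | None = None,
) -> TrialResult:
    """One simulated multi-arm trial; the test contrasts ``design.contrast``."""
    rng = np.random.default_rng(rng_seed)
    table = (
        prob_table
        if prob_table is not None
        else arm_probability_table(cohort, model, design.arms)
    )
    n_patients = table.shape[0]
    outcomes = []
    for j in range(len(design.arms)):
        idx = rng.integers(n_patients, size=design.n_per_arm)
        outcomes.append((rng.random(design.n_per_arm) < table[idx, j]).astype(float))
    i, j = design.contrast
    t, p = welch_ttest_binary(outcomes[i], outcomes[j])
    return TrialResult(
        proportions=tuple(float(y.mean()) for y in outcomes),
        statistic=float(t),
        p_value=float(p),
        n_per_arm=design.n_per_arm,
        seed=rng_seed,
    )


def estimate_power(
    cohort: Sequence[PatientRecord],
    model: OutcomeModel,
    design: TrialDesign,
    *,
    n_per_arm: int | None = None,
    replicates: int = 500,
    rng_seed: int = 0,
    prob_table: np.ndarray | None = None,
) -> PowerEstimate:
    """Rejection fraction over replicate trials, with binomial MC-SE.

    ``prob_table`` short-circuits the mechanistic per-arm simulation with
    explicit per-(patient, arm) outcome probabilities; a 1-row table
    yields the degenerate fixed-proportion design used to validate the
    engine against the analytic two-proportion formula.
    """
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    n = n_per_arm if n_per_arm is not None else design.n_per_arm
    rng = np.random.default_rng(rng_seed)
    table = (
        prob_table
        if prob_table is not None
        else arm_probability_table(cohort, model, design.arms)
    )
    p, _ = _replicate_pvalues(table, design.contrast, n, replicates, rng)
    power = float((p < design.alpha).mean())
    se = math.sqrt(max(power * (1.0 - power), 1e-12) / replicates)
    return PowerEstimate(power=power, se=se, replicates=replicates)


def power_curve(
    cohort: Sequence[PatientRecord],
    model: OutcomeModel,
    design: TrialDesign,
    n_grid: Sequence[int],
    *,
    replicates: int = 500,
    rng_seed: int = 0,
    prob_table: np.ndarray | None = None,
) -> PowerCurve:
    """Power across a grid of per-arm sample sizes."""
    table = (
        prob_table
        if prob_table is not None
        else arm_probability_table(cohort, model, design.arms)
    )
    seeds = np.random.SeedSequence(rng_seed).spawn(len(n_grid))
    powers, ses = [], []
    for n, ss in zip(n_grid, seeds):
        est = estimate_power(
            cohort,
            model,
            design,
            n_per_arm=int(n),
            replicates=replicates,
            rng_seed=int(ss.generate_state(1)[0] % 2**31),
            prob_table=table,
        )
        powers.append(est.power)
        ses.append(est.se)
    return PowerCurve(
        n_grid=tuple(int(n) for n in n_grid),
        power=tuple(powers),
        se=tuple(ses),
        replicates=replicates,
        seed=rng_seed,
    )


def find_sample_size(
    cohort: Sequence[PatientRecord],
    model: OutcomeModel,
    design: TrialDesign,
    *,
    target_power: float = 0.80,
    n_max: int = 5000,
    n_min: int = 50,
    replicates: int = 500,
    rng_seed: int = 0,
    prob_table: np.ndarray | None = None,
    mc_guard: bool = True,
) -> SampleSizeResult:
    """Smallest per-arm n whose estimated power meets the target.

    Searches a doubling grid from ``n_min`` then bisects the bracketing
    interval.  With ``mc_guard`` a size n succeeds only when
    power - 2*SE >= target, protecting the decision against Monte-Carlo
    error; the sentinel ``reached=False`` reports the power at ``n_max``
    when the target is never met.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    table = (
        prob_table
        if prob_table is not None
        else arm_probability_table(cohort, model, design.arms)
    )
    seed_seq = np.random.SeedSequence(rng_seed)

    def power_at(n: int) -> PowerEstimate:
        child = seed_seq.spawn(1)[0]
        return estimate_power(
            cohort,
            model,
            design,
            n_per_arm=n,
            replicates=replicates,
            rng_seed=int(child.generate_state(1)[0] % 2**31),
            prob_table=table,
        )

    def meets(est: PowerEstimate) -> bool:
        margin = 2.0 * est.se if mc_guard else 0.0
        return est.power - margin >= target_power

    n = n_min
    n_lo, n_hi, est_hi = None, None, None
    while n <= n_max:
        est = power_at(n)
        if meets(est):
            n_hi, est_hi = n, est
            break
        n_lo = n
        n = min(n * 2, n_max) if n < n_max else n_max + 1
    if n_hi is None:
        est = power_at(n_max)
        return SampleSizeResult(
            reached=False,
            n_per_arm=None,
            power_at_n=est.power,
            target_power=target_power,
            n_max=n_max,
            seed=rng_seed,
        )
    lo = n_lo if n_lo is not None else max(2, n_min // 2)
    while n_hi - lo > max(1, n_hi // 50):
        mid = (lo + n_hi) // 2
        est = power_at(mid)
        if meets(est):
            n_hi, est_hi = mid, est
        else:
            lo = mid
    return SampleSizeResult(
        reached=True,
        n_per_arm=n_hi,
        power_at_n=est_hi.power,
        target_power=target_power,
        n_max=n_max,
        seed=rng_seed,
    )


def two_proportion_n(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Normal-approximation per-group n for a two-proportion comparison.

    n = (z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} sqrt(p1 q1 + p2 q2))^2
        / (p1 - p2)^2, rounded up.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must lie in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 and p2 must differ")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    pbar = (p1 + p2) / 2
    num = z_a * math.sqrt(2 * pbar * (1 - pbar)) + z_b * math.sqrt(
        p1 * (1 - p1) + p2 * (1 - p2)
    )
    return int(math.ceil((num / (p1 - p2)) ** 2))


def _with_scaled_ed50(
    cohort: Sequence[PatientRecord], drug: str, multiplier: float
) -> list[PatientRecord]:
    scaled = []
    for rec in cohort:
        pkpd = dict(rec.pkpd)
        if drug in pkpd:
            pk, pd_params = pkpd[drug]
            pkpd[drug] = (pk, rescale_ed50(pd_params, multiplier))
        scaled.append(replace(rec, pkpd=pkpd))
    return scaled


def sweep_ed50(
    cohort: Sequence[PatientRecord],
    model: OutcomeModel,
    design: TrialDesign,
    multipliers: Sequence[float],
    *,
    drug: str | None = None,
    n_per_arm: int = 100,
    replicates: int = 500,
    rng_seed: int = 0,
    target_power: float = 0.80,
) -> Ed50SweepResult:
    """Power at fixed n as every patient's ED50 is rescaled.

    Larger multipliers mean a less potent drug; the interpolated crossing
    reports the potency at which the contrast is detected with the target
    power, if the sweep brackets it.
    """
    if any(m <= 0 for m in multipliers):
        raise ValueError("multipliers must be > 0")
    sweep_drug = drug if drug is not None else design.arms[0].drug
    seeds = np.random.SeedSequence(rng_seed).spawn(len(multipliers))
    powers, ses = [], []
    for mult, ss in zip(multipliers, seeds):
        scaled = _with_scaled_ed50(cohort, sweep_drug, float(mult))
        est = estimate_power(
            scaled,
            model,
            design,
            n_per_arm=n_per_arm,
            replicates=replicates,
            rng_seed=int(ss.generate_state(1)[0] % 2**31),
        )
        powers.append(est.power)
        ses.append(est.se)
    crossing = _interp_crossing(multipliers, powers, target_power)
    return Ed50SweepResult(
        multipliers=tuple(float(m) for m in multipliers),
        power=tuple(powers),
        se=tuple(ses),
        crossing=crossing,
        target_power=target_power,
    )


def _interp_crossing(
    multipliers: Sequence[float], powers: Sequence[float], target: float
) -> float | None:
    """First multiplier (in sweep order) where power crosses the target."""
    for k in range(len(powers) - 1):
        lo, hi = powers[k], powers[k + 1]
        if (lo - target) * (hi - target) <= 0 and lo != hi:
            frac = (target - lo) / (hi - lo)
            return float(multipliers[k] + frac * (multipliers[k + 1] - multipliers[k]))
    return None
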