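"""One-compartment pharmacokinetics and Hill pharmacodynamics for EA burden.

Pharmacokinetics: a single well-mixed compartment with first-order
elimination, dC/dt = input(t)/V - k_e * C.  IV boluses and constant-rate
infusions have closed-form solutions, and the linear ODE lets arbitrary
schedules be built by superposition:

* bolus of D mg/kg at t_i      ->  (D/V) * exp(-k_e (t - t_i))
* infusion at R mg/kg/h on
  [t_a, t_b]                   ->  R/(k_e V) * (1 - exp(-k_e (t - t_a)))
                                   on [t_a, t_b], decaying as
                                   C(t_b) * exp(-k_e (t - t_b)) afterwards

Pharmacodynamics: sigmoidal (Hill) suppression of the untreated burden,
S(C) = C^h / (ED50^h + C^h), where ED50 is the concentration halving the
EA burden in a 10-min window and h the Hill coefficient.  The untreated
baseline is b0 * exp(-lam * t) (constant when lam = 0) and treatment acts
multiplicatively: b(t) = baseline(t) * (1 - S(C(t))).

Per-patient parameters are estimated by minimizing the mean squared error
between simulated and observed burden trajectories.  The distribution
volume V is held fixed per drug (D/V and ED50 are jointly unidentifiable
from burden alone: no plasma concentrations enter the model) and k_e is
estimated within one decade of a literature default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from ea_trial_sim.ea_burden import (
    SEGMENTS_PER_WINDOW,
    WINDOW_MINUTES,
    BurdenSeries,
    EALabelSeries,
)

BIN_HOURS = WINDOW_MINUTES / 60.0

#: literature defaults per drug: distribution volume (L/kg, fixed) and
#: elimination rate (1/h, initialization; levetiracetam t1/2 ~ 7 h,
#: propofol effective t1/2 ~ 1 h at sedative infusion rates)
DRUG_LIBRARY: Mapping[str, Mapping[str, float]] = {
    "levetiracetam": {"V": 0.6, "k_e": np.log(2) / 7.0},
    "propofol": {"V": 4.0, "k_e": np.log(2) / 1.0},
}

ROUTES = ("bolus", "infusion_start", "infusion_stop")


@dataclass(frozen=True)
class DoseEvent:
    """A single dosing event in per-kg units, at ``time`` hours from t = 0."""

    drug: str
    time: float
    route: str
    amount: float | None = None  # mg/kg (bolus) or mg/kg/h (infusion_start)

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.route == "infusion_stop":
            if self.amount is not None:
                raise ValueError("infusion_stop carries no amount")
        elif self.amount is None or self.amount <= 0:
            raise ValueError("bolus/infusion_start amount must be > 0")


@dataclass(frozen=True)
class PKParams:
    k_e: float  # elimination rate constant, 1/h
    V: float  # distribution volume, L/kg

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k_e) and self.k_e > 0):
            raise ValueError("k_e must be positive and finite")
        if not (np.isfinite(self.V) and self.V > 0):
            raise ValueError("V must be positive and finite")


@dataclass(frozen=True)
class PDParams:
    ed50: float  # mg/L, half-suppression concentration
    hill: float  # Hill coefficient (dimensionless)
    b0: float  # untreated baseline burden at t = 0
    lam: float  # baseline decay rate, 1/h

    def __post_init__(self) -> None:
        if self.ed50 <= 0:
            raise ValueError("ed50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if not 0.0 <= self.b0 <= 1.0:
            raise ValueError("b0 must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass(frozen=True)
class ConcentrationProfile:
    times: np.ndarray  # hours
    values: np.ndarray  # mg/L

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if values.size and values.min() < -1e-12:
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", np.maximum(values, 0.0))


def time_grid(duration_h: float) -> np.ndarray:
    """Uniform 10-min grid [0, duration) in hours."""
    n = int(round(duration_h / BIN_HOURS))
    return np.arange(n) * BIN_HOURS


def _paired_infusions(events: Sequence[DoseEvent], t_end: float) -> list[tuple[float, float, float]]:
    """(t_start, t_stop, rate) intervals; an unterminated infusion runs to t_end.

    Concurrent infusions of the same drug (e.g. a randomized study
    infusion on top of a background one) are allowed: rates superpose,
    and each stop closes the earliest still-open start.
    """
    intervals: list[tuple[float, float, float]] = []
    open_starts: list[DoseEvent] = []
    for ev in sorted(events, key=lambda e: e.time):
        if ev.route == "infusion_start":
            open_starts.append(ev)
        elif ev.route == "infusion_stop":
            if not open_starts:
                raise ValueError("infusion_stop without a matching infusion_start")
            start = open_starts.pop(0)
            intervals.append((start.time, ev.time, start.amount))
    for start in open_starts:
        intervals.append((start.time, max(t_end, start.time), start.amount))
    return intervals


def concentration_profile(
    doses: Iterable[DoseEvent], pk: PKParams, times: np.ndarray
) -> ConcentrationProfile:
    """Superposed closed-form concentration of one drug on a time grid.

    All events are assumed to belong to the drug whose ``pk`` parameters
    are supplied; filter multi-drug schedules with :func:`events_for_drug`
    first.
    """
    t = np.asarray(times, dtype=float)
    c = np.zeros_like(t)
    events = list(doses)
    for ev in events:
        if ev.route == "bolus":
            dt = t - ev.time
            c += np.where(dt >= 0, (ev.amount / pk.V) * np.exp(-pk.k_e * np.maximum(dt, 0.0)), 0.0)
    t_end = float(t[-1]) if t.size else 0.0
    for t_a, t_b, rate in _paired_infusions(events, t_end):
        css = rate / (pk.k_e * pk.V)
        during = (t >= t_a) & (t <= t_b)
        after = t > t_b
        c[during] += css * (1.0 - np.exp(-pk.k_e * (t[during] - t_a)))
        c_stop = css * (1.0 - np.exp(-pk.k_e * (t_b - t_a)))
        c[after] += c_stop * np.exp(-pk.k_e * (t[after] - t_b))
    return ConcentrationProfile(times=t, values=c)


def events_for_drug(doses: Iterable[DoseEvent], drug: str) -> list[DoseEvent]:
    return [ev for ev in doses if ev.drug == drug]


def hill_suppression(c: float | np.ndarray, pd: PDParams) -> float | np.ndarray:
    """Fractional EA-burden suppression S(C) in [0, 1]."""
    arr = np.asarray(c, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(arr > 0, (arr / pd.ed50) ** pd.hill, 0.0)
    s = ratio / (1.0 + ratio)
    return float(s) if np.isscalar(c) else s


def baseline_burden(pd: PDParams, times: np.ndarray) -> np.ndarray:
    """Untreated expected burden b0 * exp(-lam t), clipped to [0, 1]."""
    return np.clip(pd.b0 * np.exp(-pd.lam * np.asarray(times, dtype=float)), 0.0, 1.0)


def simulate_burden(pd: PDParams, conc: ConcentrationProfile) -> BurdenSeries:
    """Deterministic (expected) treated burden trajectory on the 10-min grid."""
    values = baseline_burden(pd, conc.times) * (1.0 - hill_suppression(conc.values, pd))
    return BurdenSeries(times=conc.times, values=np.clip(values, 0.0, 1.0))


def simulate_burden_multidrug(
    baseline: PDParams,
    profiles: Sequence[tuple[PDParams, ConcentrationProfile]],
    times: np.ndarray,
) -> BurdenSeries:
    """Treated burden under several concurrent drugs.

    Drug effects compose multiplicatively on the surviving burden:
    b(t) = baseline(t) * prod_d (1 - S_d(C_d(t))); each drug's half-max
    concentration is its own ED50.
    """
    values = baseline_burden(baseline, times)
    for pd_params, conc in profiles:
        values = values * (1.0 - hill_suppression(conc.values, pd_params))
    return BurdenSeries(times=np.asarray(times, float), values=np.clip(values, 0.0, 1.0))


def sample_labels(burden: BurdenSeries, rng: np.random.Generator | int) -> EALabelSeries:
    """Bernoulli observation model: 300 independent labels per 10-min window."""
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = (
        gen.random((len(burden), SEGMENTS_PER_WINDOW)) < burden.values[:, None]
    ).astype(np.int8)
    return EALabelSeries(labels=labels.ravel(), start_time=float(burden.times[0]))


def sample_burden_fractions(
    burden: BurdenSeries, rng: np.random.Generator | int
) -> BurdenSeries:
    """Observed burden fractions Binomial(300, b)/300 per window.

    Distributionally identical to ``compute_burden(sample_labels(...))``
    without materializing the individual 2-sec labels.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = gen.binomial(SEGMENTS_PER_WINDOW, burden.values)
    return BurdenSeries(times=burden.times, values=counts / SEGMENTS_PER_WINDOW)


# ---------------------------------------------------------------------------
# parameter estimation


@dataclass(frozen=True)
class PkpdFit:
    """Result of per-patient PK/PD estimation."""

    pk: PKParams
    pd: PDParams
    mse: float
    pd_identifiable: bool  # False when no dose events constrain ED50/hill
    at_bounds: bool  # any estimated parameter within 1% of its box


def _mse(sim: np.ndarray, obs: np.ndarray) -> float:
    mask = np.isfinite(obs)
    return float(np.mean((sim[mask] - obs[mask]) ** 2))


def fit_pkpd(
    observed: BurdenSeries,
    doses: Sequence[DoseEvent],
    drug: str,
    *,
    v_fixed: float | None = None,
    k_e_default: float | None = None,
    n_starts: int = 8,
    max_evals: int = 2000,
    rng_seed: int = 0,
) -> PkpdFit:
    """Estimate (k_e, ED50, hill, b0, lam) by trajectory MSE minimization.

    Multi-start derivative-free search: ``n_starts`` Latin-hypercube
    initial points plus the literature default, each refined by
    bound-constrained Nelder-Mead, then a restart polish from the best
    point.  Ties are broken by lowest MSE then lowest ED50.  With no dose
    events only (b0, lam) are fitted and the PD effect parameters are
    flagged non-identifiable.
    """
    if len(observed) < 36:
        raise ValueError("need >= 36 burden bins (6 h) to fit PK/PD parameters")
    lib = DRUG_LIBRARY.get(drug, {})
    V = v_fixed if v_fixed is not None else lib.get("V")
    ke0 = k_e_default if k_e_default is not None else lib.get("k_e")
    if V is None or ke0 is None:
        raise ValueError(f"no defaults for drug {drug!r}; pass v_fixed and k_e_default")

    obs = observed.values.astype(float)
    times = observed.times.astype(float)
    drug_events = events_for_drug(doses, drug)

    if not drug_events:
        fit = _fit_baseline_only(times, obs, max_evals)
        pd_params = PDParams(ed50=1.0, hill=1.0, b0=fit[0], lam=fit[1])
        pk_params = PKParams(k_e=ke0, V=V)
        conc0 = ConcentrationProfile(times=times, values=np.zeros_like(times))
        mse = _mse(simulate_burden(pd_params, conc0).values, obs)
        return PkpdFit(pk=pk_params, pd=pd_params, mse=mse, pd_identifiable=False, at_bounds=False)

    # concentration shape depends only on k_e (V fixed): precompute per call
    def conc_values(k_e: float) -> np.ndarray:
        return concentration_profile(drug_events, PKParams(k_e=k_e, V=V), times).values

    c_ref = conc_values(ke0)
    c_scale = max(float(c_ref.max()), 1e-6)

    # search space: log10 k_e within one decade of default, log10 ed50
    # spanning the realized concentration range, log10 hill, b0, lam
    lo = np.array([np.log10(ke0) - 1.0, np.log10(c_scale) - 2.0, np.log10(0.3), 1e-6, 0.0])
    hi = np.array([np.log10(ke0) + 1.0, np.log10(c_scale) + 1.0, np.log10(10.0), 1.0, 0.2])

    def unpack(x: np.ndarray) -> tuple[float, float, float, float, float]:
        return (10.0 ** x[0], 10.0 ** x[1], 10.0 ** x[2], x[3], x[4])

    def objective(x: np.ndarray) -> float:
        k_e, ed50, hill, b0, lam = unpack(x)
        pd_params = PDParams(ed50=ed50, hill=hill, b0=b0, lam=lam)
        c = conc_values(k_e)
        sim = baseline_burden(pd_params, times) * (
            1.0 - hill_suppression(c, pd_params)
        )
        return _mse(np.clip(sim, 0.0, 1.0), obs)

    finite = obs[np.isfinite(obs)]
    b0_guess = float(np.clip(finite[: max(6, finite.size // 10)].mean(), 0.02, 0.98))
    center = np.array([np.log10(ke0), np.log10(c_scale / 2), np.log10(2.0), b0_guess, 0.005])
    sampler = qmc.LatinHypercube(d=5, seed=rng_seed)
    starts = [np.clip(center, lo, hi)]
    starts += list(qmc.scale(sampler.random(n_starts), lo, hi))

    bounds = optimize.Bounds(lo, hi)
    best_x, best_val = None, np.inf
    best_ed50 = np.inf
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-8, "fatol": 1e-10, "maxfev": max_evals},
        )
        ed50 = 10.0 ** res.x[1]
        if res.fun < best_val - 1e-15 or (
            abs(res.fun - best_val) <= 1e-15 and ed50 < best_ed50
        ):
            best_x, best_val, best_ed50 = res.x, res.fun, ed50
    # restart polish from the incumbent (fresh simplex escapes collapse)
    for _ in range(2):
        res = optimize.minimize(
            objective,
            best_x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-10, "fatol": 1e-12, "maxfev": max_evals},
        )
        if res.fun < best_val:
            best_x, best_val = res.x, res.fun

    k_e, ed50, hill, b0, lam = unpack(best_x)
    pk_params = PKParams(k_e=k_e, V=V)
    pd_params = PDParams(ed50=ed50, hill=hill, b0=b0, lam=lam)
    width = hi - lo
    at_bounds = bool(
        np.any(best_x - lo < 0.01 * width) or np.any(hi - best_x < 0.01 * width)
    )
    if at_bounds:
        warnings.warn("fit_pkpd: optimizer terminated near a parameter bound", stacklevel=2)
    mse = _mse(
        simulate_burden(
            pd_params,
            ConcentrationProfile(times=times, values=conc_values(k_e)),
        ).values,
        obs,
    )
    return PkpdFit(pk=pk_params, pd=pd_params, mse=mse, pd_identifiable=True, at_bounds=at_bounds)


def _fit_baseline_only(
    times: np.ndarray, obs: np.ndarray, max_evals: int
) -> tuple[float, float]:
    """(b0, lam) for an untreated record."""
    mask = np.isfinite(obs)

    def objective(x: np.ndarray) -> float:
        sim = np.clip(x[0] * np.exp(-x[1] * times), 0.0, 1.0)
        return float(np.mean((sim[mask] - obs[mask]) ** 2))

    finite = obs[mask]
    x0 = np.array([np.clip(finite.mean(), 1e-3, 1.0), 0.0])
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=optimize.Bounds([0.0, 0.0], [1.0, 0.2]),
        options={"xatol": 1e-10, "fatol": 1e-12, "maxfev": max_evals},
    )
    return float(res.x[0]), float(res.x[1])


def rescale_ed50(pd: PDParams, multiplier: float) -> PDParams:
    """PD parameters with ED50 scaled by ``multiplier`` (drug-potency sweep)."""
    if multiplier <= 0:
        raise ValueError("ED50 multiplier must be > 0")
    return replace(pd, ed50=pd.ed50 * multiplier)
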