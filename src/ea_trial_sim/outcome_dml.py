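"""Doubly robust outcome modeling for dichotomized discharge mRS.

Discharge functional outcome (modified Rankin Scale, dichotomized good
0-3 / poor 4-6) is modeled as a function of the EA-burden summary E_max
and the average drug concentration during treatment, adjusting for
baseline covariates and the per-patient PK/PD parameters as confounders.

The treatment-effect estimates use double/debiased machine learning with
cross-fitting: gradient-boosted trees learn the nuisance regressions
E[Y | X] and E[T_j | X] on held-out folds, and the effect vector theta is
obtained by regressing the outcome residuals on the exposure residuals
(partialling-out estimator for the partially linear model
Y = theta' T + g(X) + eps).  Squared-loss partialling-out gives theta a
linear-probability interpretation (percentage-point change in P(poor) per
unit exposure).  A separate gradient-boosted classifier g_hat predicts
P(poor | E_max, mean concentration, X) for the trial engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.model_selection import KFold

from ea_trial_sim.records import PatientRecord

#: gradient-boosting settings shared by all nuisance fits (small-n stability)
GBT_PARAMS: Mapping[str, float | int] = {
    "n_estimators": 200,
    "max_depth": 3,
    "learning_rate": 0.05,
}

#: probability clip applied before Bernoulli outcome draws in trials
PROB_CLIP = (0.01, 0.99)

EXPOSURE_COLUMNS = ("e_max", "mean_conc")


def dichotomize_mrs(mrs: int) -> str:
    """Map mRS 0-3 to ``"good"`` and 4-6 to ``"poor"``."""
    m = int(mrs)
    if m != mrs or not 0 <= m <= 6:
        raise ValueError("mrs must be an integer in 0..6")
    return "poor" if m >= 4 else "good"


def is_poor(mrs: int) -> bool:
    return dichotomize_mrs(mrs) == "poor"


@dataclass(frozen=True)
class ExposureSummary:
    """Per-patient exposure: E_max and mean drug concentration (mg/L)."""

    e_max: float
    mean_conc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_max <= 1.0:
            raise ValueError("e_max must lie in [0, 1]")
        if self.mean_conc < 0:
            raise ValueError("mean_conc must be >= 0")


def confounder_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Design matrix of baseline covariates and PK/PD parameters.

    Sex is one-hot (``sex_M``); ordinal severity grades enter as
    integers; per-drug elimination rate, ED50 and Hill coefficient plus
    the shared baseline (b0, lam) represent treatment-response
    heterogeneity.
    """
    rows = []
    for rec in records:
        cov = rec.covariates
        row: dict[str, float] = {
            "age": cov.age,
            "sex_M": 1.0 if cov.sex == "M" else 0.0,
            "hunt_hess": float(cov.hunt_hess),
            "fisher": float(cov.fisher),
            "time_to_eeg": cov.time_to_eeg,
            "eeg_duration": cov.eeg_duration,
            "weight": cov.weight,
        }
        base = rec.baseline_pd()
        row["b0"] = base.b0
        row["lam"] = base.lam
        for drug in sorted(rec.pkpd):
            pk, pd_params = rec.pkpd[drug]
            row[f"{drug}_k_e"] = pk.k_e
            row[f"{drug}_ed50"] = pd_params.ed50
            row[f"{drug}_hill"] = pd_params.hill
        rows.append(row)
    return pd.DataFrame(rows, index=[rec.patient_id for rec in records])


@dataclass
class OutcomeModel:
    """Cross-fitted DML effect estimates plus an outcome-probability predictor."""

    theta: np.ndarray  # effect per exposure component, prob. scale
    theta_se: np.ndarray  # heteroskedasticity-robust standard errors
    exposure_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    identifiable: np.ndarray  # per component; False for constant exposure
    fold_assignment: np.ndarray
    nuisance_y: np.ndarray  # cross-fitted E[Y|X] predictions
    nuisance_t: np.ndarray  # cross-fitted E[T|X], one column per exposure
    classifier: GradientBoostingClassifier
    seed: int
    n_folds: int

    def confidence_interval(self, component: int = 0, z: float = 1.96) -> tuple[float, float]:
        est, se = self.theta[component], self.theta_se[component]
        return est - z * se, est + z * se


def dml_partialling_out(
    X: np.ndarray,
    T: np.ndarray,
    Y: np.ndarray,
    *,
    n_folds: int = 5,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cross-fitted partialling-out estimator for a partially linear model.

    Returns ``(theta, theta_se, fold_assignment, m_y, m_t)`` where ``m_y``
    and ``m_t`` are the cross-fitted nuisance predictions for the outcome
    and each exposure column.  For each fold the nuisances are trained on
    the complementary folds only, so residuals are out-of-sample.
    """
    X = np.asarray(X, dtype=float)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape[0] != X.shape[0]:
        T = T.T
    Y = np.asarray(Y, dtype=float)
    n, d_t = T.shape
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} observations for {n_folds}-fold cross-fitting")

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    fold_assignment = np.empty(n, dtype=int)
    m_y = np.empty(n)
    m_t = np.empty((n, d_t))
    for k, (train, test) in enumerate(kf.split(X)):
        fold_assignment[test] = k
        reg_y = GradientBoostingRegressor(random_state=rng_seed, **GBT_PARAMS)
        reg_y.fit(X[train], Y[train])
        m_y[test] = reg_y.predict(X[test])
        for j in range(d_t):
            reg_t = GradientBoostingRegressor(random_state=rng_seed + 1 + j, **GBT_PARAMS)
            reg_t.fit(X[train], T[train, j])
            m_t[test, j] = reg_t.predict(X[test])

    v = T - m_t  # exposure residuals
    u = Y - m_y  # outcome residuals
    gram = v.T @ v
    identifiable = np.std(T, axis=0) > 1e-12
    theta = np.full(d_t, np.nan)
    se = np.full(d_t, np.nan)
    cols = np.flatnonzero(identifiable)
    if cols.size:
        g = gram[np.ix_(cols, cols)]
        theta_sub = np.linalg.solve(g, v[:, cols].T @ u)
        eps = u - v[:, cols] @ theta_sub
        meat = (v[:, cols] * eps[:, None]).T @ (v[:, cols] * eps[:, None])
        ginv = np.linalg.inv(g)
        cov = ginv @ meat @ ginv
        theta[cols] = theta_sub
        se[cols] = np.sqrt(np.diag(cov))
    return theta, se, fold_assignment, m_y, m_t


def fit_outcome_model(
    cohort: Sequence[PatientRecord],
    exposures: Sequence[ExposureSummary],
    *,
    n_folds: int = 5,
    rng_seed: int = 0,
) -> OutcomeModel:
    """Fit the DML effect estimates and the arm-level outcome predictor.

    ``exposures`` must align with ``cohort``.  Raises on a degenerate
    outcome (all good or all poor); a constant exposure component is
    flagged non-identifiable rather than raising.
    """
    if len(cohort) != len(exposures):
        raise ValueError("cohort and exposures must align")
    if any(rec.mrs is None for rec in cohort):
        raise ValueError("all records need an observed discharge mRS")
    Y = np.array([1.0 if is_poor(rec.mrs) else 0.0 for rec in cohort])
    if Y.min() == Y.max():
        raise ValueError("degenerate outcome: all patients in one mRS class")
    Xf = confounder_frame(cohort)
    T = np.column_stack(
        [[e.e_max for e in exposures], [e.mean_conc for e in exposures]]
    )
    theta, se, folds, m_y, m_t = dml_partialling_out(
        Xf.to_numpy(), T, Y, n_folds=n_folds, rng_seed=rng_seed
    )
    identifiable = ~np.isnan(theta)

    clf = GradientBoostingClassifier(random_state=rng_seed, **GBT_PARAMS)
    features = np.column_stack([T, Xf.to_numpy()])
    clf.fit(features, Y)
    return OutcomeModel(
        theta=theta,
        theta_se=se,
        exposure_names=EXPOSURE_COLUMNS,
        feature_names=EXPOSURE_COLUMNS + tuple(Xf.columns),
        identifiable=identifiable,
        fold_assignment=folds,
        nuisance_y=m_y,
        nuisance_t=m_t,
        classifier=clf,
        seed=rng_seed,
        n_folds=n_folds,
    )


def _feature_rows(
    model: OutcomeModel,
    exposures: Sequence[ExposureSummary],
    records: Sequence[PatientRecord],
) -> np.ndarray:
    Xf = confounder_frame(records)
    missing = [c for c in model.feature_names[2:] if c not in Xf.columns]
    if missing:
        raise ValueError(f"records lack confounder columns {missing}")
    T = np.column_stack(
        [[e.e_max for e in exposures], [e.mean_conc for e in exposures]]
    )
    return np.column_stack([T, Xf[list(model.feature_names[2:])].to_numpy()])


def predict_outcome(
    model: OutcomeModel,
    exposure: ExposureSummary,
    record: PatientRecord,
) -> float:
    """P(poor outcome | exposure, covariates), clipped to [0.01, 0.99]."""
    return float(predict_outcome_batch(model, [exposure], [record])[0])


def predict_outcome_batch(
    model: OutcomeModel,
    exposures: Sequence[ExposureSummary],
    records: Sequence[PatientRecord],
) -> np.ndarray:
    """Vectorized :func:`predict_outcome` over aligned exposures/records."""
    feats = _feature_rows(model, exposures, records)
    p = model.classifier.predict_proba(feats)[:, 1]
    return np.clip(p, *PROB_CLIP)
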