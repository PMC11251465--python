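"""Tabular I/O, configuration, run manifests and the pipeline driver.

Cohorts are exchanged as four CSV files (UTF-8, comma-separated, header
row mandatory, floats at 9 significant digits):

* ``patients.csv``    patient_id, age, sex, hunt_hess, fisher,
                      time_to_eeg, eeg_duration, weight, mrs
* ``pkpd_params.csv`` patient_id, drug, k_e, V, ed50, hill, b0, lam
* ``doses.csv``       patient_id, drug, time_h, route, amount
* ``burden.csv``      patient_id, window_start_hour, burden

All times are hours from the first EA measurement (t = 0); intervals are
half-open [start, end).  Every stochastic stage's seed is captured in a
run manifest written before any results.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ea_trial_sim import __version__
from ea_trial_sim.ea_burden import BurdenSeries
from ea_trial_sim.outcome_dml import ExposureSummary, fit_outcome_model
from ea_trial_sim.pkpd import DoseEvent, PDParams, PKParams, fit_pkpd
from ea_trial_sim.records import Covariates, PatientRecord
from ea_trial_sim.synthetic_cohort import CohortConfig, GeneratedCohort, generate_cohort
from ea_trial_sim.trial_engine import (
    Regimen,
    TrialDesign,
    apply_regimen,
    find_sample_size,
    power_curve,
    standard_arms,
    sweep_ed50,
)

FLOAT_FMT = "%.9g"

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "hunt_hess",
    "fisher",
    "time_to_eeg",
    "eeg_duration",
    "weight",
    "mrs",
]


def save_cohort(records: list[PatientRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write the four cohort CSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, params, doses, burden = [], [], [], []
    for rec in records:
        c = rec.covariates
        patients.append(
            {
                "patient_id": rec.patient_id,
                "age": c.age,
                "sex": c.sex,
                "hunt_hess": c.hunt_hess,
                "fisher": c.fisher,
                "time_to_eeg": c.time_to_eeg,
                "eeg_duration": c.eeg_duration,
                "weight": c.weight,
                "mrs": rec.mrs,
            }
        )
        for drug, (pk, pd_params) in sorted(rec.pkpd.items()):
            params.append(
                {
                    "patient_id": rec.patient_id,
                    "drug": drug,
                    "k_e": pk.k_e,
                    "V": pk.V,
                    "ed50": pd_params.ed50,
                    "hill": pd_params.hill,
                    "b0": pd_params.b0,
                    "lam": pd_params.lam,
                }
            )
        for ev in rec.doses:
            doses.append(
                {
                    "patient_id": rec.patient_id,
                    "drug": ev.drug,
                    "time_h": ev.time,
                    "route": ev.route,
                    "amount": ev.amount if ev.amount is not None else "",
                }
            )
        if rec.burden is not None:
            for t, v in zip(rec.burden.times, rec.burden.values):
                burden.append(
                    {"patient_id": rec.patient_id, "window_start_hour": t, "burden": v}
                )
    paths = {}
    for name, rows, cols in (
        ("patients", patients, PATIENT_COLUMNS),
        ("pkpd_params", params, None),
        ("doses", doses, None),
        ("burden", burden, None),
    ):
        path = out / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format=FLOAT_FMT)
        paths[name] = path
    return paths


def _fail(table: str, row: int, msg: str) -> None:
    raise ValueError(f"{table}.csv row {row}: {msg}")


def load_cohort(in_dir: str | Path) -> list[PatientRecord]:
    """Read and validate the cohort CSVs; errors carry table + row number."""
    d = Path(in_dir)
    pats = pd.read_csv(d / "patients.csv")
    if list(pats.columns) != PATIENT_COLUMNS:
        raise ValueError(f"patients.csv: expected columns {PATIENT_COLUMNS}")
    if pats["patient_id"].duplicated().any():
        dup = pats.loc[pats["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"patients.csv: duplicated patient_id {dup!r}")
    params = pd.read_csv(d / "pkpd_params.csv")
    doses_path = d / "doses.csv"
    doses = pd.read_csv(doses_path) if doses_path.exists() else pd.DataFrame()
    burden = pd.read_csv(d / "burden.csv")

    records = []
    for i, row in pats.iterrows():
        pid = row["patient_id"]
        try:
            cov = Covariates(
                age=float(row["age"]),
                sex=str(row["sex"]),
                hunt_hess=int(row["hunt_hess"]),
                fisher=int(row["fisher"]),
                time_to_eeg=float(row["time_to_eeg"]),
                eeg_duration=float(row["eeg_duration"]),
                weight=float(row["weight"]),
            )
        except ValueError as exc:
            _fail("patients", i + 2, str(exc))
        pkpd = {}
        for j, prow in params[params["patient_id"] == pid].iterrows():
            try:
                pkpd[str(prow["drug"])] = (
                    PKParams(k_e=float(prow["k_e"]), V=float(prow["V"])),
                    PDParams(
                        ed50=float(prow["ed50"]),
                        hill=float(prow["hill"]),
                        b0=float(prow["b0"]),
                        lam=float(prow["lam"]),
                    ),
                )
            except ValueError as exc:
                _fail("pkpd_params", j + 2, str(exc))
        events = []
        if len(doses):
            for j, drow in doses[doses["patient_id"] == pid].iterrows():
                amount = drow.get("amount")
                try:
                    events.append(
                        DoseEvent(
                            drug=str(drow["drug"]),
                            time=float(drow["time_h"]),
                            route=str(drow["route"]),
                            amount=None if pd.isna(amount) else float(amount),
                        )
                    )
                except ValueError as exc:
                    _fail("doses", j + 2, str(exc))
        sub = burden[burden["patient_id"] == pid]
        if sub.empty:
            raise ValueError(f"burden.csv: no burden series for patient {pid!r}")
        series = BurdenSeries(
            times=sub["window_start_hour"].to_numpy(float),
            values=sub["burden"].to_numpy(float),
        )
        mrs = row["mrs"]
        records.append(
            PatientRecord(
                patient_id=pid,
                covariates=cov,
                pkpd=pkpd,
                doses=tuple(events),
                burden=series,
                mrs=None if pd.isna(mrs) else int(mrs),
            )
        )
    return records


# ---------------------------------------------------------------------------
# run manifest and pipeline


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict = field(default_factory=dict)
    version: str = __version__
    started: float = 0.0
    completed_stages: list = field(default_factory=list)
    file_digests: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(path.read_text()))


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Chain generate -> fit-pkpd -> fit-outcome -> power/sample-size/sweep.

    Each stage writes its artifacts under ``out_dir`` and is skipped on
    rerun when its outputs already exist for the same configuration
    (digests recorded in the manifest).  Seeds for every stage derive
    from the top-level ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(
            ["generate", "fit_pkpd", "fit_outcome", "trials"],
            np.random.SeedSequence(seed).spawn(4),
        )
    }
    chash = config_hash(config)
    manifest_path = out / "manifest.json"
    manifest = RunManifest(config_hash=chash, seeds=stage_seeds, started=time.time())
    if manifest_path.exists():
        prior = RunManifest.read(manifest_path)
        if prior.config_hash == chash:
            manifest = prior
            manifest.seeds = stage_seeds
    manifest.write(manifest_path)

    def done(stage: str, *paths: Path) -> bool:
        return stage in manifest.completed_stages and all(p.exists() for p in paths)

    def finish(stage: str, *paths: Path) -> None:
        if stage not in manifest.completed_stages:
            manifest.completed_stages.append(stage)
        for p in paths:
            manifest.file_digests[p.name] = _digest(p)
        manifest.write(manifest_path)

    # --- generate ---------------------------------------------------------
    cohort_dir = out / "cohort"
    truth_path = out / "ground_truth.csv"
    if not done("generate", truth_path):
        cohort_cfg = CohortConfig(
            seed=stage_seeds["generate"], **config.get("cohort", {})
        )
        gen = generate_cohort(cohort_cfg)
        save_cohort(gen.records, cohort_dir)
        gen.truth.to_csv(truth_path, float_format=FLOAT_FMT)
        finish("generate", truth_path)
    records = load_cohort(cohort_dir)

    # --- fit-pkpd ---------------------------------------------------------
    fits_path = out / "pkpd_fits.csv"
    fit_cfg = config.get("fit_pkpd", {})
    if fit_cfg.get("enabled", True):
        if not done("fit_pkpd", fits_path):
            rows = []
            for rec in records:
                for drug in sorted(rec.pkpd):
                    fit = fit_pkpd(
                        rec.burden,
                        list(rec.doses),
                        drug,
                        n_starts=int(fit_cfg.get("n_starts", 8)),
                        max_evals=int(fit_cfg.get("max_evals", 2000)),
                        rng_seed=stage_seeds["fit_pkpd"],
                    )
                    rows.append(
                        {
                            "patient_id": rec.patient_id,
                            "drug": drug,
                            "k_e": fit.pk.k_e,
                            "V": fit.pk.V,
                            "ed50": fit.pd.ed50,
                            "hill": fit.pd.hill,
                            "b0": fit.pd.b0,
                            "lam": fit.pd.lam,
                            "mse": fit.mse,
                            "pd_identifiable": fit.pd_identifiable,
                            "at_bounds": fit.at_bounds,
                        }
                    )
            pd.DataFrame(rows).to_csv(fits_path, index=False, float_format=FLOAT_FMT)
            finish("fit_pkpd", fits_path)
        records = apply_fitted_params(records, pd.read_csv(fits_path))

    # --- fit-outcome ------------------------------------------------------
    exposures = [
        apply_regimen(rec, Regimen(drug="levetiracetam", kind="placebo"))[0]
        for rec in records
    ]
    model = fit_outcome_model(
        records,
        exposures,
        n_folds=int(config.get("outcome", {}).get("n_folds", 5)),
        rng_seed=stage_seeds["fit_outcome"],
    )
    theta_path = out / "outcome_theta.json"
    theta_path.write_text(
        json.dumps(
            {
                "theta": dict(zip(model.exposure_names, model.theta.tolist())),
                "se": dict(zip(model.exposure_names, model.theta_se.tolist())),
                "seed": model.seed,
                "n_folds": model.n_folds,
            },
            indent=2,
        )
    )
    finish("fit_outcome", theta_path)

    # --- trials -----------------------------------------------------------
    trial_cfg = config.get("trial", {})
    drug = trial_cfg.get("drug", "levetiracetam")
    arms = standard_arms(drug)
    design = TrialDesign(
        arms=tuple(arms),
        n_per_arm=int(trial_cfg.get("n_per_arm", 100)),
        alpha=float(trial_cfg.get("alpha", 0.05)),
        contrast=tuple(trial_cfg.get("contrast", (1, 3))),
    )
    replicates = int(trial_cfg.get("replicates", 500))
    n_grid = [int(n) for n in trial_cfg.get("n_grid", [50, 100, 200, 400, 800])]
    curve = power_curve(
        records, model, design, n_grid, replicates=replicates, rng_seed=stage_seeds["trials"]
    )
    curve_path = out / "power_curve.csv"
    pd.DataFrame(
        {"n_per_arm": curve.n_grid, "power": curve.power, "mc_se": curve.se}
    ).to_csv(curve_path, index=False, float_format=FLOAT_FMT)
    result = find_sample_size(
        records,
        model,
        design,
        target_power=float(config.get("sample_size", {}).get("target_power", 0.80)),
        n_max=int(config.get("sample_size", {}).get("n_max", 5000)),
        replicates=replicates,
        rng_seed=stage_seeds["trials"],
    )
    ss_path = out / "sample_size.json"
    ss_path.write_text(
        json.dumps(
            {
                "reached": result.reached,
                "n_per_arm": result.n_per_arm,
                "n_total": None
                if result.n_per_arm is None
                else result.n_per_arm * len(design.arms),
                "power_at_n": result.power_at_n,
                "target_power": result.target_power,
                "n_max": result.n_max,
                "seed": result.seed,
            },
            indent=2,
        )
    )
    finish("trials", curve_path, ss_path)

    sweep_cfg = config.get("sweep")
    if sweep_cfg:
        sweep = sweep_ed50(
            records,
            model,
            design,
            multipliers=[float(m) for m in sweep_cfg.get("multipliers", [0.25, 0.5, 1, 2, 4])],
            n_per_arm=int(sweep_cfg.get("n_per_arm", 100)),
            replicates=replicates,
            rng_seed=stage_seeds["trials"],
        )
        sweep_path = out / "ed50_sweep.csv"
        pd.DataFrame(
            {"multiplier": sweep.multipliers, "power": sweep.power, "mc_se": sweep.se}
        ).to_csv(sweep_path, index=False, float_format=FLOAT_FMT)
        finish("sweep", sweep_path)
    return manifest


def apply_fitted_params(
    records: list[PatientRecord], fits: pd.DataFrame
) -> list[PatientRecord]:
    """Replace each record's PK/PD parameters with fitted estimates."""
    from dataclasses import replace

    out = []
    for rec in records:
        sub = fits[fits["patient_id"] == rec.patient_id]
        pkpd = dict(rec.pkpd)
        for _, row in sub.iterrows():
            pkpd[str(row["drug"])] = (
                PKParams(k_e=float(row["k_e"]), V=float(row["V"])),
                PDParams(
                    ed50=float(row["ed50"]),
                    hill=float(row["hill"]),
                    b0=float(row["b0"]),
                    lam=float(row["lam"]),
                ),
            )
        out.append(replace(rec, pkpd=pkpd))
    return out
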