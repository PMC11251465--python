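"""Power curves and minimal sample sizes for the simulated trials.

For each drug, simulates randomized trials with three active-dose arms
plus placebo (active regimens added on top of background standard care),
contrasts the median-dose arm against placebo and the high-dose arm
against the median dose, and reports the per-arm n needed for 80% power
at alpha 0.05 with a two-sided t-test.  Writes per-drug power-curve CSVs
and results/sample_sizes.json.
"""

import json
from pathlib import Path

import pandas as pd

from ea_trial_sim.io import apply_fitted_params, load_cohort
from ea_trial_sim.outcome_dml import fit_outcome_model
from ea_trial_sim.trial_engine import (
    Regimen,
    TrialDesign,
    apply_regimen,
    find_sample_size,
    power_curve,
    standard_arms,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 13
N_GRID = [50, 100, 200, 400, 800]
REPLICATES = 500
CONTRASTS = {"mid_vs_placebo": (1, 3), "high_vs_mid": (0, 1)}


def main() -> None:
    records = load_cohort(RESULTS / "cohort")
    records = apply_fitted_params(records, pd.read_csv(RESULTS / "pkpd_fits.csv"))
    exposures = [
        apply_regimen(rec, Regimen("levetiracetam", "placebo"))[0] for rec in records
    ]
    model = fit_outcome_model(records, exposures, rng_seed=12)

    sample_sizes = {}
    for drug in ("levetiracetam", "propofol"):
        arms = standard_arms(drug)
        for label, contrast in CONTRASTS.items():
            design = TrialDesign(
                arms=tuple(arms), n_per_arm=100, alpha=0.05, contrast=contrast
            )
            curve = power_curve(
                records, model, design, N_GRID, replicates=REPLICATES, rng_seed=SEED
            )
            out = RESULTS / f"power_{drug}_{label}.csv"
            pd.DataFrame(
                {"n_per_arm": curve.n_grid, "power": curve.power, "mc_se": curve.se}
            ).to_csv(out, index=False, float_format="%.9g")
            res = find_sample_size(
                records, model, design,
                target_power=0.80, n_max=5000,
                replicates=REPLICATES, rng_seed=SEED,
            )
            key = f"{drug}:{label}"
            sample_sizes[key] = {
                "reached": res.reached,
                "n_per_arm": res.n_per_arm,
                "n_total": None if res.n_per_arm is None else res.n_per_arm * len(arms),
                "power_at_n": res.power_at_n,
            }
            arm_pair = f"{arms[contrast[0]].label} vs {arms[contrast[1]].label}"
            if res.reached:
                print(f"{key}: n >= {res.n_per_arm}/arm for 80% power ({arm_pair})")
            else:
                print(f"{key}: did not reach 80% power by n={res.n_max}/arm "
                      f"(power {res.power_at_n:.2f}) ({arm_pair})")
    (RESULTS / "sample_sizes.json").write_text(json.dumps(sample_sizes, indent=2))
    print(f"wrote power curves and {RESULTS / 'sample_sizes.json'}")


if __name__ == "__main__":
    main()
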