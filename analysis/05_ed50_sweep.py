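"""Drug-potency sweep: power at fixed n as levetiracetam's ED50 is rescaled.

At 100 patients per arm, rescales every patient's levetiracetam ED50 by a
grid of multipliers (smaller = more potent drug) and re-estimates the
power of the median-dose-vs-placebo contrast, locating the potency at
which the trial reaches 80% power.  Writes results/ed50_sweep.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ea_trial_sim.io import apply_fitted_params, load_cohort
from ea_trial_sim.outcome_dml import fit_outcome_model
from ea_trial_sim.trial_engine import (
    Regimen,
    TrialDesign,
    apply_regimen,
    standard_arms,
    sweep_ed50,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 14
MULTIPLIERS = list(np.geomspace(0.02, 8.0, 9))


def main() -> None:
    records = load_cohort(RESULTS / "cohort")
    records = apply_fitted_params(records, pd.read_csv(RESULTS / "pkpd_fits.csv"))
    exposures = [
        apply_regimen(rec, Regimen("levetiracetam", "placebo"))[0] for rec in records
    ]
    model = fit_outcome_model(records, exposures, rng_seed=12)
    design = TrialDesign(
        arms=tuple(standard_arms("levetiracetam")),
        n_per_arm=100,
        alpha=0.05,
        contrast=(1, 3),  # median dose vs placebo
    )
    sweep = sweep_ed50(
        records, model, design, MULTIPLIERS,
        drug="levetiracetam", n_per_arm=100, replicates=500, rng_seed=SEED,
    )
    pd.DataFrame(
        {"multiplier": sweep.multipliers, "power": sweep.power, "mc_se": sweep.se}
    ).to_csv(RESULTS / "ed50_sweep.csv", index=False, float_format="%.9g")
    for m, p, s in zip(sweep.multipliers, sweep.power, sweep.se):
        print(f"  ED50 x {m:6.3f}: power {p:.3f} (MC-SE {s:.3f})")
    if sweep.crossing is not None:
        print(f"80% power crossed at ED50 multiplier ~{sweep.crossing:.3f}")
    else:
        print("80% power not bracketed by this multiplier grid at n=100/arm")
    print(f"wrote {RESULTS / 'ed50_sweep.csv'}")


if __name__ == "__main__":
    main()
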