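"""The cohort atom: covariates, PK/PD parameters, dosing, burden, outcome."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ea_trial_sim.ea_burden import BurdenSeries
from ea_trial_sim.pkpd import DoseEvent, PDParams, PKParams

SEXES = ("F", "M")


@dataclass(frozen=True)
class Covariates:
    """Baseline covariates measured at hospitalization."""

    age: float  # years
    sex: str  # F / M
    hunt_hess: int  # clinical severity grade, 1-5
    fisher: int  # radiographic severity grade, 1-4
    time_to_eeg: float  # hours from admission to cEEG start
    eeg_duration: float  # hours of cEEG monitoring
    weight: float  # kg

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if not 1 <= self.hunt_hess <= 5:
            raise ValueError("hunt_hess must be in 1..5")
        if not 1 <= self.fisher <= 4:
            raise ValueError("fisher must be in 1..4")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.age <= 0 or self.time_to_eeg < 0 or self.eeg_duration <= 0:
            raise ValueError("age/eeg timing fields out of range")


@dataclass(frozen=True)
class PatientRecord:
    """One patient: the unit resampled by the trial engine.

    ``pkpd`` maps drug name to that drug's (PK, PD) parameter pair; the
    baseline components (b0, lam) are a patient property and agree across
    drugs.  ``doses`` is the observed (or generator-assigned) background
    standard-care schedule, retained under every randomized arm.
    """

    patient_id: str
    covariates: Covariates
    pkpd: Mapping[str, tuple[PKParams, PDParams]]
    doses: Sequence[DoseEvent] = field(default_factory=tuple)
    burden: BurdenSeries | None = None
    mrs: int | None = None

    def __post_init__(self) -> None:
        if self.mrs is not None and not 0 <= int(self.mrs) <= 6:
            raise ValueError("mrs must be an integer in 0..6")

    def baseline_pd(self) -> PDParams:
        """Shared untreated-baseline parameters (from any drug entry)."""
        if not self.pkpd:
            raise ValueError(f"patient {self.patient_id} has no PK/PD parameters")
        return next(iter(self.pkpd.values()))[1]
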