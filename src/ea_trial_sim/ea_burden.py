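"""Epileptiform-activity (EA) burden quantification.

Continuous-EEG segments of 2 seconds are labelled 0/1 for the presence of
epileptiform activity (seizures, LPDs, GPDs, LRDA pooled into one
category).  Burden is the fraction of positive segments in consecutive,
non-overlapping 10-minute windows; the exposure summary driving the
outcome model is ``E_max``, the maximum mean burden over 6-hour sliding
windows of the burden series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: seconds per labelled EEG segment
SEGMENT_SECONDS = 2
#: minutes per burden aggregation window
WINDOW_MINUTES = 10
#: 2-sec segments per complete 10-min window
SEGMENTS_PER_WINDOW = WINDOW_MINUTES * 60 // SEGMENT_SECONDS  # 300
#: burden bins per 6-hour E_max window
EMAX_WINDOW_BINS = 6 * 60 // WINDOW_MINUTES  # 36


@dataclass(frozen=True)
class EALabelSeries:
    """Dense binary EA labels, one per 2-second EEG segment.

    ``start_time`` is in hours from the first EA measurement (t = 0).
    """

    labels: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 1 or labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must contain only 0/1")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class BurdenSeries:
    """EA fraction per non-overlapping 10-minute window.

    ``times`` are window start times in hours, uniformly spaced at 10 min.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1 or times.size < 1:
            raise ValueError("times and values must be matching non-empty 1-D arrays")
        if values.min() < 0.0 or values.max() > 1.0:
            raise ValueError("burden values must lie in [0, 1]")
        if times.size > 1:
            dt = np.diff(times)
            if not np.allclose(dt, WINDOW_MINUTES / 60.0, atol=1e-9):
                raise ValueError("times must increase uniformly by 10 minutes")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class EaSummary:
    """Exposure summaries of a burden series."""

    e_max: float
    mean_burden: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_max <= 1.0:
            raise ValueError("e_max must lie in [0, 1]")


def compute_burden(labels: EALabelSeries) -> BurdenSeries:
    """Aggregate 2-sec labels into 10-minute burden fractions.

    One value per complete window of 300 segments; a trailing partial
    window is dropped.  Raises ``ValueError`` when the record is shorter
    than one complete window.
    """
    arr = labels.labels
    n_windows = arr.size // SEGMENTS_PER_WINDOW
    if n_windows < 1:
        raise ValueError(
            f"record too short: {arr.size} labels < {SEGMENTS_PER_WINDOW} "
            "(one complete 10-min window)"
        )
    trimmed = arr[: n_windows * SEGMENTS_PER_WINDOW]
    values = trimmed.reshape(n_windows, SEGMENTS_PER_WINDOW).mean(axis=1)
    times = labels.start_time + np.arange(n_windows) * (WINDOW_MINUTES / 60.0)
    return BurdenSeries(times=times, values=values)


def compute_emax(burden: BurdenSeries) -> float:
    """Maximum EA fraction among 6-hour sliding windows.

    The window slides by one 10-min bin (36 consecutive bins per window).
    A record shorter than 6 hours degenerates to a single whole-record
    window, i.e. the overall mean.
    """
    values = burden.values
    if values.size == 0:
        raise ValueError("empty burden series")
    if values.size < EMAX_WINDOW_BINS:
        return float(values.mean())
    # mean over every 36-bin window via cumulative sums
    csum = np.concatenate(([0.0], np.cumsum(values)))
    window_sums = csum[EMAX_WINDOW_BINS:] - csum[:-EMAX_WINDOW_BINS]
    return float(window_sums.max() / EMAX_WINDOW_BINS)


def mean_burden(burden: BurdenSeries) -> float:
    """Arithmetic mean of the burden series."""
    if len(burden) == 0:
        raise ValueError("empty burden series")
    return float(burden.values.mean())


def summarize(burden: BurdenSeries) -> EaSummary:
    """E_max and overall mean burden of a series."""
    return EaSummary(e_max=compute_emax(burden), mean_burden=mean_burden(burden))
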