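"""Desaturation-event detection and oximetry feature computation.

A desaturation event is a drop of at least a configured depth (2-5 % by
default) below the running pre-event baseline — the mean saturation over the
preceding 120 s — lasting strictly more than 10 s.  The baseline is frozen
at the event onset so that long desaturations are not absorbed into their
own baseline; the event closes when saturation recovers above
(frozen baseline − smallest depth threshold).

From the detected events the eight standard nocturnal-oximetry features are
computed: hourly desaturation rates at depth ≥ 2/3/4/5 % (ndes2ph..ndes5ph),
the oxygen desaturation indices odi3/odi4 (identical to ndes3ph/ndes4ph
under this single-detector reading — both count ≥3 %/≥4 % events per hour),
and the cumulative time indices pctle90/pctle92 (percent of analyzable time
spent at or below 90 %/92 % saturation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .signal_io import FEATURE_COLUMNS, SpO2Record, validate_signal

__all__ = [
    "DetectorConfig",
    "DesatEvent",
    "FeatureVector",
    "BaselineUndefined",
    "UndefinedFeaturesError",
    "compute_baseline",
    "detect_events",
    "compute_features",
    "label_subject",
    "severity_class",
    "events_to_frame",
    "HEALTHY",
    "AT_RISK",
]

HEALTHY = "healthy"
AT_RISK = "at_risk"

#: screening cutoff on the apnea/hypopnea index, events per hour
AHI_CUTOFF = 5.0


class BaselineUndefined(Exception):
    """Raised when too little valid history exists to define a baseline."""


class UndefinedFeaturesError(Exception):
    """Raised when a record has zero analyzable time."""


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable thresholds of the desaturation detector.

    baseline_window_s
        Length of the pre-event averaging window (seconds).
    min_baseline_history_s
        Minimum valid history inside the window for the baseline to be
        defined; earlier samples cannot open events.
    min_duration_s
        Events must last strictly longer than this (seconds).
    depth_thresholds_pct
        Ordered desaturation depths (percent below baseline) at which
        events are counted.
    odi_depths_pct
        Depths used for the oxygen desaturation indices.
    sat_time_thresholds_pct
        Absolute saturation cutoffs for the cumulative time indices.
    """

    baseline_window_s: float = 120.0
    min_baseline_history_s: float = 30.0
    min_duration_s: float = 10.0
    depth_thresholds_pct: tuple = (2.0, 3.0, 4.0, 5.0)
    odi_depths_pct: tuple = (3.0, 4.0)
    sat_time_thresholds_pct: tuple = (90.0, 92.0)

    def __post_init__(self) -> None:
        if self.baseline_window_s <= 0 or self.min_duration_s <= 0:
            raise ValueError("window and duration thresholds must be positive")
        depths = tuple(self.depth_thresholds_pct)
        if list(depths) != sorted(depths) or len(set(depths)) != len(depths):
            raise ValueError("depth thresholds must be strictly increasing")


@dataclass(frozen=True)
class DesatEvent:
    """One detected desaturation, as a half-open sample interval."""

    onset_index: int
    offset_index: int
    baseline_pct: float
    depth_pct: float
    duration_s: float

    def onset_s(self, rate: float) -> float:
        return self.onset_index / rate

    def offset_s(self, rate: float) -> float:
        return self.offset_index / rate


@dataclass
class FeatureVector:
    """The eight oximetry features for one subject, plus optional label."""

    odi3: float
    odi4: float
    ndes2ph: float
    ndes3ph: float
    ndes4ph: float
    ndes5ph: float
    pctle90: float
    pctle92: float
    ahi: Optional[float] = None
    label: Optional[str] = None
    subject_id: Optional[str] = None

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in FEATURE_COLUMNS}
        if self.subject_id is not None:
            d = {"subject_id": self.subject_id, **d}
        if self.ahi is not None:
            d["ahi"] = self.ahi
        if self.label is not None:
            d["label"] = self.label
        return d


def compute_baseline(
    record: SpO2Record, index: int, config: DetectorConfig = DetectorConfig()
) -> float:
    """Mean valid saturation over the window preceding ``index``.

    Uses the window [index − baseline_window, index); if less of the record
    exists, whatever history is available.  Raises :class:`BaselineUndefined`
    when fewer than ``min_baseline_history_s`` seconds of valid samples are
    available.
    """
    if not 0 <= index <= record.n_samples:
        raise IndexError(index)
    rate = record.sampling_rate
    w = int(round(config.baseline_window_s * rate))
    lo = max(0, index - w)
    window = record.values[lo:index]
    mask = record.valid_mask[lo:index]
    n_valid = int(mask.sum())
    if n_valid < config.min_baseline_history_s * rate:
        raise BaselineUndefined(
            f"only {n_valid / rate:.0f} s of valid history before sample {index}"
        )
    return float(window[mask].mean())


def detect_events(
    record: SpO2Record, config: DetectorConfig = DetectorConfig()
) -> List[DesatEvent]:
    """Detect desaturation events against the running pre-event baseline.

    Scans at the smallest configured depth threshold; an event opens at the
    first valid sample at or below (baseline − depth), with the baseline
    frozen at its onset value, and closes at the first sample back above
    that level.  Deeper-threshold detections are always sub-intervals of
    this one, so each physical desaturation is recorded once with
    ``depth_pct`` equal to the maximum drop achieved.  Events containing an
    invalid sample are discarded (depth and duration cannot be certified
    through a dropout), as are events not strictly longer than the minimum
    duration.  Returned events are non-overlapping and sorted by onset.
    """
    if record.analyzable_s is None:
        record = validate_signal(record)
    events: List[DesatEvent] = []
    if record.analyzable_s == 0:
        import warnings

        warnings.warn("record has zero analyzable time; no events detected")
        return events

    rate = record.sampling_rate
    d_min = min(config.depth_thresholds_pct)
    min_dur = config.min_duration_s
    values, mask = record.values, record.valid_mask
    n = record.n_samples

    # incremental valid-sample window sums for O(n) baselines
    w = int(round(config.baseline_window_s * rate))
    min_hist = config.min_baseline_history_s * rate
    csum = np.concatenate([[0.0], np.cumsum(np.where(mask, values, 0.0))])
    ccnt = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])

    def baseline_at(i: int) -> Optional[float]:
        lo = max(0, i - w)
        cnt = ccnt[i] - ccnt[lo]
        if cnt < min_hist:
            return None
        return (csum[i] - csum[lo]) / cnt

    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        b = baseline_at(i)
        if b is None or values[i] > b - d_min:
            i += 1
            continue
        # candidate event; baseline frozen at onset
        onset = i
        j = i
        aborted = False
        while j < n:
            if not mask[j]:
                aborted = True
                break
            if values[j] > b - d_min:
                break
            j += 1
        if aborted:
            i = j + 1
            continue
        duration_s = (j - onset) / rate
        if duration_s > min_dur:
            depth = b - float(values[onset:j].min())
            events.append(DesatEvent(onset, j, b, depth, duration_s))
        i = j
    return events


def compute_features(
    record: SpO2Record,
    events: Sequence[DesatEvent],
    config: DetectorConfig = DetectorConfig(),
    ahi: Optional[float] = None,
) -> FeatureVector:
    """Aggregate detected events into the eight oximetry features."""
    if record.analyzable_s is None:
        record = validate_signal(record)
    hours = record.analyzable_s / 3600.0
    if hours == 0:
        raise UndefinedFeaturesError("zero analyzable time")
    depths = np.array([e.depth_pct for e in events], dtype=float)

    def rate_at(d: float) -> float:
        return float((depths >= d).sum()) / hours

    valid = record.valid_mask
    vals = record.values
    sec_per_sample = 1.0 / record.sampling_rate
    analyzable = record.analyzable_s

    def pct_at_or_below(t: float) -> float:
        secs = float((valid & (vals <= t)).sum()) * sec_per_sample
        return 100.0 * secs / analyzable

    t90, t92 = config.sat_time_thresholds_pct
    label = None if ahi is None else label_subject(ahi)
    return FeatureVector(
        odi3=rate_at(config.odi_depths_pct[0]),
        odi4=rate_at(config.odi_depths_pct[1]),
        ndes2ph=rate_at(config.depth_thresholds_pct[0]),
        ndes3ph=rate_at(config.depth_thresholds_pct[1]),
        ndes4ph=rate_at(config.depth_thresholds_pct[2]),
        ndes5ph=rate_at(config.depth_thresholds_pct[3]),
        pctle90=pct_at_or_below(t90),
        pctle92=pct_at_or_below(t92),
        ahi=ahi,
        label=label,
        subject_id=record.subject_id,
    )


def label_subject(ahi: float, cutoff: float = AHI_CUTOFF) -> str:
    """Screening label from the apnea/hypopnea index: at_risk iff AHI ≥ cutoff."""
    if ahi < 0:
        raise ValueError(f"AHI must be non-negative, got {ahi}")
    return AT_RISK if ahi >= cutoff else HEALTHY


def severity_class(ahi: float) -> str:
    """Clinical severity bin: normal <5, mild 5-15, moderate 15-30, severe ≥30."""
    if ahi < 0:
        raise ValueError(f"AHI must be non-negative, got {ahi}")
    if ahi < 5:
        return "normal"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def events_to_frame(record: SpO2Record, events: Sequence[DesatEvent]) -> pd.DataFrame:
    """Events as a CSV-ready table (times in seconds from record start)."""
    rate = record.sampling_rate
    return pd.DataFrame(
        {
            "subject_id": [record.subject_id] * len(events),
            "onset_s": [e.onset_s(rate) for e in events],
            "offset_s": [e.offset_s(rate) for e in events],
            "duration_s": [e.duration_s for e in events],
            "baseline_pct": [e.baseline_pct for e in events],
            "depth_pct": [e.depth_pct for e in events],
        }
    )
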