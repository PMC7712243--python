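"""Shared fixtures: synthetic records and a naive reference event detector."""

from __future__ import annotations

import numpy as np
import pytest

from oxiscreen.desat import DetectorConfig
from oxiscreen.signal_io import SpO2Record, validate_signal


def make_record(values, rate=1.0, subject_id="test", mask=None):
    """Build a validated record from a plain value sequence."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.size, dtype=bool)
    return validate_signal(SpO2Record(subject_id, rate, values, mask))


def naive_detect(record, config: DetectorConfig = DetectorConfig()):
    """Per-sample reference detector, written for obviousness not speed.

    Walks the record one sample at a time, recomputing the pre-event
    baseline by direct summation over the preceding window; opens an event
    when the sample sits at or below (baseline − smallest depth), freezes
    that baseline, closes on recovery above the same level, keeps events
    strictly longer than the minimum duration, and discards any candidate
    interrupted by an invalid sample.  Returns (onset, offset, baseline,
    depth) tuples.
    """
    vals, mask = record.values, record.valid_mask
    rate = record.sampling_rate
    n = vals.size
    w = int(round(config.baseline_window_s * rate))
    min_hist = config.min_baseline_history_s * rate
    d_min = min(config.depth_thresholds_pct)
    out = []
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        lo = max(0, i - w)
        window = [vals[j] for j in range(lo, i) if mask[j]]
        if len(window) < min_hist:
            i += 1
            continue
        b = sum(window) / len(window)
        if vals[i] > b - d_min:
            i += 1
            continue
        j = i
        aborted = False
        while j < n:
            if not mask[j]:
                aborted = True
                break
            if vals[j] > b - d_min:
                break
            j += 1
        if aborted:
            i = j + 1
            continue
        if (j - i) / rate > config.min_duration_s:
            depth = b - min(vals[i:j])
            out.append((i, j, b, depth))
        i = j
    return out


@pytest.fixture(scope="session")
def flat_record():
    """One hour at a constant 98 % saturation."""
    return make_record(np.full(3600, 98.0))


@pytest.fixture(scope="session")
def reference_cohort():
    """The default synthetic two-group cohort (197 healthy / 256 at-risk)."""
    from oxiscreen.synth import CohortSpec, make_cohort

    return make_cohort(CohortSpec(seed=42))
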