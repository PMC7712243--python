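"""Synthetic SpO2 traces and feature cohorts with known ground truth.

Two generators make the pipeline testable without access to clinical sleep
studies:

``make_trace``
    An overnight saturation trace: piecewise-constant baseline near 97 %,
    Gaussian sensor noise, desaturation events injected as trapezoidal dips
    with configurable depth/duration/rate at Poisson-thinned onsets, and
    optional zero-valued dropouts.  The injected events are returned as
    ground truth, spaced further apart than the detector's baseline window
    so they are individually recoverable.

``make_cohort``
    Per-subject feature vectors for a two-group cohort (healthy vs at-risk
    of obstructive sleep apnea, screening cutoff AHI = 5).  Default group
    means and SDs reproduce the published summary statistics of a pediatric
    polysomnography cohort of 197 healthy and 256 at-risk children; each
    feature is drawn from a Gaussian truncated at 0.  A clustered mode
    couples the desaturation-rate features through a shared latent severity
    factor to reproduce their strong (|r| > 0.9) empirical correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .desat import AT_RISK, HEALTHY, label_subject
from .signal_io import FEATURE_COLUMNS, SpO2Record, validate_signal

__all__ = [
    "TraceSpec",
    "CohortSpec",
    "InjectedEvent",
    "make_trace",
    "make_cohort",
    "DEFAULT_GROUP_STATS",
    "truncated_mean",
]

#: (mean, SD) per feature for the healthy and at-risk groups; defaults match
#: the published group summaries of a 197/256 pediatric cohort
DEFAULT_GROUP_STATS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "odi3": {HEALTHY: (2.79, 2.08), AT_RISK: (10.53, 7.38)},
    "odi4": {HEALTHY: (0.98, 0.83), AT_RISK: (5.53, 4.81)},
    "ndes2ph": {HEALTHY: (82.91, 58.31), AT_RISK: (189.94, 107.56)},
    "ndes3ph": {HEALTHY: (28.13, 20.45), AT_RISK: (91.67, 63.06)},
    "ndes4ph": {HEALTHY: (10.08, 8.44), AT_RISK: (47.17, 40.32)},
    "ndes5ph": {HEALTHY: (4.41, 4.49), AT_RISK: (26.51, 26.97)},
    "pctle90": {HEALTHY: (0.06, 0.69), AT_RISK: (0.29, 0.51)},
    "pctle92": {HEALTHY: (0.38, 3.49), AT_RISK: (0.81, 1.37)},
}

#: features coupled through the latent severity factor in clustered mode
SEVERITY_CLUSTER = ["odi3", "odi4", "ndes2ph", "ndes3ph", "ndes4ph", "ndes5ph"]


class SpecError(ValueError):
    """An infeasible or inconsistent generator specification."""


@dataclass(frozen=True)
class InjectedEvent:
    """Ground truth for one injected desaturation."""

    onset_index: int
    offset_index: int
    depth_pct: float       # nominal depth below local baseline
    duration_s: float      # time below (baseline - min detector depth)

    def as_dict(self) -> dict:
        return {
            "onset_index": self.onset_index,
            "offset_index": self.offset_index,
            "depth_pct": self.depth_pct,
            "duration_s": self.duration_s,
        }


@dataclass
class TraceSpec:
    """Parameters of one synthetic overnight recording (1 Hz).

    ``depth_distribution`` maps nominal event depth (percent below
    baseline) to probability; depths sit mid-way between detector
    thresholds by default so noise does not flip the depth class.
    ``min_gap_s`` keeps events further apart than the detector's 120-s
    baseline window, making the ground truth recoverable.
    """

    duration_h: float = 8.0
    baseline_sat_pct: float = 97.0
    event_rate_per_h: float = 5.0
    depth_distribution: Dict[float, float] = field(
        default_factory=lambda: {2.5: 0.25, 3.5: 0.30, 4.5: 0.20, 5.5: 0.15, 6.5: 0.07, 7.5: 0.03}
    )
    duration_range_s: Tuple[float, float] = (12.0, 60.0)
    noise_sd_pct: float = 0.2
    baseline_jitter_pct: float = 0.4
    dropout_rate_per_h: float = 0.0
    dropout_duration_s: Tuple[float, float] = (5.0, 30.0)
    min_gap_s: float = 150.0
    ramp_pct_per_s: float = 0.5
    detector_min_depth_pct: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.noise_sd_pct < 0:
            raise SpecError("duration must be positive, noise non-negative")
        occupancy = self.event_rate_per_h * (self.min_gap_s + self.duration_range_s[1])
        if occupancy > 3600.0:
            raise SpecError(
                f"infeasible rate: {self.event_rate_per_h}/h events with "
                f"{self.min_gap_s}s gaps exceed one hour of occupancy"
            )


def _dip_profile(depth: float, below_s: float, ramp: float, d_min: float) -> np.ndarray:
    """Clean trapezoidal dip, sampled at 1 Hz, as negative offsets.

    Shaped so the time spent below ``d_min`` percent under baseline is
    approximately ``below_s`` seconds.
    """
    hold = max(below_s - 2.0 * (depth - d_min) / ramp, 1.0)
    t_ramp = depth / ramp
    total = int(np.ceil(2 * t_ramp + hold)) + 1
    t = np.arange(total, dtype=float)
    down = np.minimum(t * ramp, depth)
    up = np.minimum((total - 1 - t) * ramp, depth)
    return -np.minimum(np.minimum(down, up), depth)


def make_trace(spec: TraceSpec) -> Tuple[SpO2Record, List[InjectedEvent]]:
    """Generate a synthetic SpO2 record and its injected-event ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_h * 3600))
    # piecewise-constant baseline, 30-min segments with small level shifts
    baseline = np.empty(n)
    seg = 1800
    for start in range(0, n, seg):
        level = spec.baseline_sat_pct + rng.uniform(
            -spec.baseline_jitter_pct, spec.baseline_jitter_pct
        )
        baseline[start : start + seg] = min(level, 99.5)
    clean = baseline.copy()

    # Hard-core renewal placement: each accepted event is followed by the
    # minimum gap plus an exponential waiting time whose mean is chosen so
    # the marginal onset rate equals the nominal events/hour.
    depths = np.array(sorted(spec.depth_distribution))
    probs = np.array([spec.depth_distribution[d] for d in depths])
    probs = probs / probs.sum()
    d_min = spec.detector_min_depth_pct
    truth: List[InjectedEvent] = []
    if spec.event_rate_per_h > 0:
        mean_below = float(np.mean(spec.duration_range_s))
        mean_span = mean_below + 2.0 * d_min / spec.ramp_pct_per_s + 1.0
        mean_wait = 3600.0 / spec.event_rate_per_h - spec.min_gap_s - mean_span
        if mean_wait <= 0:
            raise SpecError(
                f"infeasible rate {spec.event_rate_per_h}/h with "
                f"min_gap_s={spec.min_gap_s}: no room for exponential waits"
            )
        t = spec.min_gap_s + rng.exponential(mean_wait)
        while True:
            depth = float(rng.choice(depths, p=probs))
            below_s = float(rng.uniform(*spec.duration_range_s))
            profile = _dip_profile(depth, below_s, spec.ramp_pct_per_s, d_min)
            i0 = int(round(t))
            i1 = i0 + profile.size
            if i1 >= n:
                break
            clean[i0:i1] += profile
            seg_base = baseline[i0]
            below = np.flatnonzero(clean[i0:i1] <= seg_base - d_min)
            if below.size:
                ev_on, ev_off = int(i0 + below[0]), int(i0 + below[-1] + 1)
                truth.append(InjectedEvent(ev_on, ev_off, depth, float(ev_off - ev_on)))
            else:  # dip cancelled by a baseline step; withdraw it
                clean[i0:i1] -= profile
            t = i1 + spec.min_gap_s + rng.exponential(mean_wait)

    values = clean + rng.normal(0.0, spec.noise_sd_pct, size=n)
    np.clip(values, 0.0, 100.0, out=values)

    # dropouts: runs of zeros, kept clear of injected events
    n_drop = rng.poisson(spec.dropout_rate_per_h * spec.duration_h)
    forbidden = [(e.onset_index - int(spec.min_gap_s), e.offset_index + int(spec.min_gap_s))
                 for e in truth]
    for _ in range(n_drop):
        for _attempt in range(100):
            dur = int(rng.uniform(*spec.dropout_duration_s))
            start = int(rng.uniform(0, n - dur))
            if all(start + dur <= lo or start >= hi for lo, hi in forbidden):
                values[start : start + dur] = 0.0
                break

    record = SpO2Record(
        subject_id=f"synth-{spec.seed}",
        sampling_rate=1.0,
        values=values,
        valid_mask=np.ones(n, dtype=bool),
    )
    return validate_signal(record), truth


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group feature cohort."""

    n_healthy: int = 197
    n_at_risk: int = 256
    group_stats: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_STATS.items()}
    )
    coupling: str = "independent"  # or "clustered"
    cluster_rho: float = 0.95
    attach_ahi: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 1 or self.n_at_risk < 1:
            raise SpecError("group sizes must be at least 1")
        for feat, groups in self.group_stats.items():
            for grp, (_, sd) in groups.items():
                if sd <= 0:
                    raise SpecError(f"non-positive SD for {feat}/{grp}")
        if self.coupling not in ("independent", "clustered"):
            raise SpecError(f"unknown coupling {self.coupling!r}")


def truncated_mean(mean: float, sd: float) -> float:
    """Theoretical mean of N(mean, sd) truncated to [0, inf)."""
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd))


def _draw_group(
    spec: CohortSpec, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    if spec.coupling == "clustered":
        z = rng.standard_normal(n)  # latent severity factor
    for feat in FEATURE_COLUMNS:
        mean, sd = spec.group_stats[feat][group]
        if spec.coupling == "clustered" and feat in SEVERITY_CLUSTER:
            eps = rng.standard_normal(n)
            x = mean + sd * (np.sqrt(spec.cluster_rho) * z
                             + np.sqrt(1 - spec.cluster_rho) * eps)
            cols[feat] = np.clip(x, 0.0, None)
        else:
            a = (0.0 - mean) / sd
            cols[feat] = stats.truncnorm.rvs(
                a, np.inf, loc=mean, scale=sd, size=n, random_state=rng
            )
    df = pd.DataFrame(cols)
    if spec.attach_ahi:
        if group == HEALTHY:
            df["ahi"] = rng.uniform(0.0, 5.0, size=n)
        else:
            df["ahi"] = rng.uniform(5.0, 30.0, size=n)
    df["label"] = group
    return df


def make_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a labeled two-group cohort from the configured group statistics."""
    rng = np.random.default_rng(spec.seed)
    healthy = _draw_group(spec, HEALTHY, spec.n_healthy, rng)
    at_risk = _draw_group(spec, AT_RISK, spec.n_at_risk, rng)
    df = pd.concat([healthy, at_risk], ignore_index=True)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(df))])
    return CohortTable(df)


def truth_to_json(truth: List[InjectedEvent], path) -> None:
    """Write the ground-truth sidecar for a generated trace."""
    with open(path, "w") as fh:
        json.dump([e.as_dict() for e in truth], fh, indent=1)
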