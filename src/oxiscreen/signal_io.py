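"""Reading, validating and writing overnight SpO2 recordings.

Overnight pulse-oximetry traces arrive either as an EDF channel (the format
sleep labs distribute) or as a plain two-column time/SpO2 CSV.  Both are
resampled on load to a fixed analysis rate (1 Hz by default, block-median
decimation) so that downstream event-duration thresholds are expressed in
whole samples regardless of the recording device.

EDF reading is delegated to :mod:`mne`.  No installed library writes EDF, so
a minimal single-channel 16-bit EDF writer is provided here; it exists to
round-trip synthetic traces and covers only what this package emits.
"""

from __future__ import annotations

import datetime as _dt
import io
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpO2Record",
    "FEATURE_COLUMNS",
    "SignalIOError",
    "ChannelNotFoundError",
    "EmptySignalError",
    "FormatError",
    "DEFAULT_CHANNEL_ALIASES",
    "ANALYSIS_RATE_HZ",
    "read_edf",
    "write_edf",
    "read_csv",
    "write_csv",
    "validate_signal",
    "write_feature_table",
    "read_feature_table",
]

#: canonical feature order used across the package and in feature-table CSVs
FEATURE_COLUMNS = [
    "odi3",
    "odi4",
    "ndes2ph",
    "ndes3ph",
    "ndes4ph",
    "ndes5ph",
    "pctle90",
    "pctle92",
]

#: analysis sampling rate after load, Hz
ANALYSIS_RATE_HZ = 1.0

#: case-insensitive channel names accepted as the oximetry channel
DEFAULT_CHANNEL_ALIASES = ["SpO2", "SaO2", "OSAT", "Oximetry"]

#: saturations below this are not physiological and are masked invalid
SAT_FLOOR_PCT = 50.0
SAT_CEIL_PCT = 100.0

#: invalid runs longer than this are removed from analyzable time, seconds
DEFAULT_MAX_GAP_S = 60.0


class SignalIOError(Exception):
    """Base class for signal input/output failures."""


class ChannelNotFoundError(SignalIOError):
    """No oximetry channel matched the configured aliases."""


class EmptySignalError(SignalIOError):
    """The file contained no usable samples."""


class FormatError(SignalIOError):
    """The file violates the expected layout (e.g. non-monotone time)."""


@dataclass
class SpO2Record:
    """A uniformly sampled oxygen-saturation trace.

    Parameters
    ----------
    subject_id : str
        Opaque identifier carried through to feature tables.
    sampling_rate : float
        Samples per second; constant across the record.
    values : ndarray of float
        Saturation in percent.  Invalid samples keep their raw value but are
        masked out.
    valid_mask : ndarray of bool
        True where the sample is a physiologically plausible reading.
    start_time : datetime, optional
        Wall-clock time of the first sample.
    analyzable_s : float, optional
        Seconds of analyzable recording, set by :func:`validate_signal`
        (total duration minus invalid runs longer than the configured gap).
    """

    subject_id: str
    sampling_rate: float
    values: np.ndarray
    valid_mask: np.ndarray
    start_time: Optional[_dt.datetime] = None
    analyzable_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.ndim != 1 or self.values.size < 1:
            raise EmptySignalError("record needs at least one sample")
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must have equal length")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


def _block_median_resample(
    t: np.ndarray, x: np.ndarray, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bin samples into 1/rate-second bins and take the median per bin.

    Bins with no samples are returned as NaN (masked invalid later).
    """
    dt_out = 1.0 / rate
    n_out = int(math.ceil((t[-1] - t[0] + 1e-9) / dt_out))
    n_out = max(n_out, 1)
    idx = np.floor((t - t[0]) / dt_out).astype(np.int64)
    idx = np.clip(idx, 0, n_out - 1)
    out = np.full(n_out, np.nan)
    order = np.argsort(idx, kind="stable")
    idx_s, x_s = idx[order], x[order]
    bounds = np.searchsorted(idx_s, np.arange(n_out + 1))
    for j in range(n_out):
        lo, hi = bounds[j], bounds[j + 1]
        if hi > lo:
            out[j] = np.median(x_s[lo:hi])
    return out, np.isfinite(out)


def _apply_validity(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mask dropouts (SpO2 == 0) and readings outside the plausible band."""
    bad = ~np.isfinite(values)
    bad |= values < SAT_FLOOR_PCT  # includes the zero-dropout convention
    bad |= values > SAT_CEIL_PCT
    return mask & ~bad


def read_edf(
    path: os.PathLike | str,
    channel_name: Optional[str] = None,
    aliases: Sequence[str] = DEFAULT_CHANNEL_ALIASES,
    analysis_rate: float = ANALYSIS_RATE_HZ,
    subject_id: Optional[str] = None,
) -> SpO2Record:
    """Load the oximetry channel of an EDF file.

    ``channel_name`` pins an exact channel (case-insensitive); otherwise the
    first channel matching one of ``aliases`` is used.  The signal is
    resampled to ``analysis_rate`` by block median and validated.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    wanted = [channel_name] if channel_name else list(aliases)
    picked = None
    for cand in wanted:
        for name in names:
            if name.strip().lower() == cand.strip().lower():
                picked = name
                break
        if picked:
            break
    if picked is None:
        raise ChannelNotFoundError(
            f"no oximetry channel among {names!r}; looked for {wanted!r}"
        )
    data = raw.get_data(picks=[picked])[0]
    # mne rescales unknown channel units to SI; undo a 1e-2 or 1e-6 factor
    # if the data no longer look like percent saturation
    finite = data[np.isfinite(data)]
    if finite.size and np.nanmax(np.abs(finite)) <= 1.5:
        data = data * 100.0
    elif finite.size and np.nanmax(np.abs(finite)) <= 150e-6:
        data = data * 1e6
    if data.size == 0:
        raise EmptySignalError(f"channel {picked!r} in {path} is empty")
    sfreq = float(raw.info["sfreq"])
    t = np.arange(data.size) / sfreq
    values, mask = _block_median_resample(t, data, analysis_rate)
    mask = _apply_validity(values, mask)
    sid = subject_id or os.path.splitext(os.path.basename(str(path)))[0]
    meas_date = raw.info.get("meas_date")
    start = None
    if meas_date is not None:
        start = _dt.datetime.fromtimestamp(meas_date.timestamp())
    return validate_signal(
        SpO2Record(sid, analysis_rate, values, mask, start_time=start)
    )


def read_csv(
    path: os.PathLike | str,
    time_col: str = "time_s",
    spo2_col: str = "spo2_pct",
    analysis_rate: float = ANALYSIS_RATE_HZ,
    subject_id: Optional[str] = None,
) -> SpO2Record:
    """Load a two-column time/SpO2 CSV.

    The native rate is inferred from the median time delta; the trace is
    resampled to ``analysis_rate`` (block median) and validated.  Rows with
    non-numeric SpO2 are masked invalid; non-monotone timestamps are a
    format error.
    """
    df = pd.read_csv(path)
    for col in (time_col, spo2_col):
        if col not in df.columns:
            raise FormatError(f"column {col!r} not in {list(df.columns)}")
    t = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
    x = pd.to_numeric(df[spo2_col], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(t)
    t, x = t[keep], x[keep]
    if t.size < 2:
        raise EmptySignalError(f"{path}: fewer than 2 usable rows")
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: timestamps not strictly increasing")
    values, mask = _block_median_resample(t, x, analysis_rate)
    mask = _apply_validity(values, mask)
    sid = subject_id or os.path.splitext(os.path.basename(str(path)))[0]
    return validate_signal(SpO2Record(sid, analysis_rate, values, mask))


def write_csv(record: SpO2Record, path: os.PathLike | str, precision: int = 2) -> None:
    """Write a record as time_s,spo2_pct rows (invalid samples as 0)."""
    t = np.arange(record.n_samples) / record.sampling_rate
    vals = np.where(record.valid_mask, record.values, 0.0)
    df = pd.DataFrame({"time_s": t, "spo2_pct": np.round(vals, precision)})
    df.to_csv(path, index=False)


def validate_signal(
    record: SpO2Record, max_gap_s: float = DEFAULT_MAX_GAP_S
) -> SpO2Record:
    """Apply the validity rules and compute analyzable time.

    Samples outside [50, 100] percent (including the SpO2 = 0 dropout
    convention) are masked invalid.  Runs of invalid samples longer than
    ``max_gap_s`` are excluded from analyzable time; shorter gaps still
    count (the surrounding signal is continuous enough to interpret).
    Idempotent.
    """
    mask = _apply_validity(record.values, np.ones_like(record.valid_mask)) & record.valid_mask
    n = record.n_samples
    rate = record.sampling_rate
    gap_samples = int(round(max_gap_s * rate))
    excluded = 0
    i = 0
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            if (j - i) > gap_samples:
                excluded += j - i
            i = j
        else:
            i += 1
    analyzable = (n - excluded) / rate
    return replace(record, valid_mask=mask, analyzable_s=analyzable)


def write_feature_table(df: pd.DataFrame, path: os.PathLike | str) -> None:
    """Write a per-subject feature table CSV with canonical column order."""
    cols = ["subject_id"] + FEATURE_COLUMNS
    for opt in ("ahi", "label"):
        if opt in df.columns:
            cols.append(opt)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing columns {missing}")
    df.loc[:, cols].to_csv(path, index=False)


def read_feature_table(path: os.PathLike | str) -> pd.DataFrame:
    """Read a feature table CSV, checking the canonical feature columns."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Minimal EDF writer (single channel, 16-bit, 1-second data records).
# ---------------------------------------------------------------------------

def _edf_field(text: str, width: int) -> bytes:
    s = text[:width].ljust(width)
    return s.encode("ascii")


def write_edf(
    record: SpO2Record,
    path: os.PathLike | str,
    channel_name: str = "SpO2",
) -> None:
    """Write a single-channel EDF file.

    Samples are quantised to the EDF 16-bit integer range over a fixed
    physical range of 0-100 percent; invalid samples are written as 0
    (the dropout convention recovered on read).  The record duration is
    padded to a whole number of 1-second data records.
    """
    rate = record.sampling_rate
    spr = max(int(round(rate)), 1)  # samples per 1-s data record
    vals = np.where(record.valid_mask, record.values, 0.0)
    n_rec = int(math.ceil(vals.size / spr))
    padded = np.zeros(n_rec * spr)
    padded[: vals.size] = vals
    phys_min, phys_max = 0.0, 100.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * scale + dig_min).astype("<i2")

    start = record.start_time or _dt.datetime(2000, 1, 1, 22, 0, 0)
    hdr = io.BytesIO()
    hdr.write(_edf_field("0", 8))                      # version
    hdr.write(_edf_field(f"X {record.subject_id}", 80))  # patient id
    hdr.write(_edf_field("Startdate X X X X", 80))     # recording id
    hdr.write(_edf_field(start.strftime("%d.%m.%y"), 8))
    hdr.write(_edf_field(start.strftime("%H.%M.%S"), 8))
    hdr.write(_edf_field(str(256 + 256), 8))           # header bytes
    hdr.write(_edf_field("", 44))                      # reserved
    hdr.write(_edf_field(str(n_rec), 8))
    hdr.write(_edf_field("1", 8))                      # record duration s
    hdr.write(_edf_field("1", 4))                      # n signals
    hdr.write(_edf_field(channel_name, 16))
    hdr.write(_edf_field("pulse oximeter", 80))
    hdr.write(_edf_field("%", 8))
    hdr.write(_edf_field(f"{phys_min:g}", 8))
    hdr.write(_edf_field(f"{phys_max:g}", 8))
    hdr.write(_edf_field(str(dig_min), 8))
    hdr.write(_edf_field(str(dig_max), 8))
    hdr.write(_edf_field("", 80))                      # prefiltering
    hdr.write(_edf_field(str(spr), 8))
    hdr.write(_edf_field("", 32))                      # reserved per signal
    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        fh.write(digital.tobytes())
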