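"""Filtering, artifact-segment rejection, and the participant-exclusion rule.

The cleaning contract mirrors a standard resting-state pipeline: a 0.1 Hz
high-pass to remove slow drift, a 50 Hz notch for mains interference (both
applied zero-phase, forward-backward, so filter delay cancels), rejection
of fixed-length segments whose peak amplitude exceeds a threshold on any
analysis channel, and exclusion of subjects for whom more than 25% of the
recording was discarded. Amplitude-threshold rejection stands in for the
manual, ICA-assisted artifact screening used with real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .recording import Recording

HP_CUTOFF_HZ = 0.1
NOTCH_HZ = 50.0
NOTCH_Q = 25.0
HP_ORDER = 4
EXCLUSION_RETENTION = 0.75  # retained fraction at or above this is kept


def apply_filters(
    rec: Recording,
    hp_hz: float = HP_CUTOFF_HZ,
    notch_hz: float = NOTCH_HZ,
    notch_q: float = NOTCH_Q,
) -> Recording:
    """Zero-phase 0.1 Hz high-pass plus 50 Hz notch; returns a filtered copy."""
    if rec.fs < 128:
        raise ValueError("sampling rate below 128 Hz is not supported")
    if notch_hz >= rec.fs / 2:
        raise ValueError(
            f"notch at {notch_hz} Hz is at or above Nyquist ({rec.fs / 2} Hz)"
        )
    out = rec.copy()
    sos = signal.butter(HP_ORDER, hp_hz, btype="highpass", fs=rec.fs, output="sos")
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)
    out.data = signal.filtfilt(b, a, out.data, axis=1)
    return out


def downsample(rec: Recording, target_fs: float = 128.0) -> Recording:
    """Anti-aliased integer-factor downsampling (research-grade recordings
    are reduced to the consumer rate so Welch grids match)."""
    if rec.fs == target_fs:
        return rec.copy()
    q, r = divmod(rec.fs, target_fs)
    if r != 0:
        raise ValueError(f"{rec.fs} Hz is not an integer multiple of {target_fs} Hz")
    q = int(q)
    data = signal.resample_poly(rec.data, up=1, down=q, axis=1)
    n = data.shape[1]
    # a downsampled block is retained only if its whole source block was
    mask = rec.retained[: n * q].reshape(n, q).all(axis=1) \
        if rec.retained.size >= n * q else np.ones(n, dtype=bool)
    # the polyphase FIR smears rejected-sample energy into neighbours;
    # erode the retained mask by the filter's half-width on each side
    margin = 11  # samples at target rate; default kaiser filter half-length 10/q
    if not mask.all():
        bad = ~mask
        kernel = np.ones(2 * margin + 1, dtype=bool)
        bad = np.convolve(bad, kernel, mode="same") > 0
        mask = ~bad
    return Recording(
        subject=rec.subject, system=rec.system, fs=target_fs,
        channels=tuple(rec.channels), data=data, retained=mask,
    )


def reject_segments(
    rec: Recording,
    seg_len_s: float = 1.0,
    amp_threshold_uv: float = 100.0,
) -> tuple[Recording, float]:
    """Drop fixed-length segments whose peak |amplitude| exceeds threshold.

    The retained mask is updated in the returned copy; the fraction of
    segments retained is returned alongside. Zero retained segments is a
    flagged (fraction 0.0) result, not an exception.
    """
    seg = int(round(seg_len_s * rec.fs))
    n_segs = rec.n_samples // seg
    if n_segs < 4:
        raise ValueError("segment length must divide the recording at least 4 times")
    out = rec.copy()
    peaks = np.abs(
        out.data[:, : n_segs * seg].reshape(len(rec.channels), n_segs, seg)
    ).max(axis=(0, 2))
    bad = peaks > amp_threshold_uv
    mask = out.retained
    for i in np.flatnonzero(bad):
        mask[i * seg: (i + 1) * seg] = False
    mask[n_segs * seg:] = False  # trailing partial segment is dropped
    out.retained = mask
    return out, float(1.0 - bad.mean())


@dataclass
class RetentionReport:
    table: pd.DataFrame  # subject, system, retention, excluded
    mean_retention: float
    min_retention: float
    max_retention: float
    n_excluded: int

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def retained_subjects(self) -> list[str]:
        return list(self.table.loc[~self.table.excluded, "subject"])


def apply_exclusion_rule(
    retention: pd.DataFrame, threshold: float = EXCLUSION_RETENTION
) -> RetentionReport:
    """Mark subjects excluded when retention falls below 75%.

    The rule reads "more than 25% discarded", so a subject at exactly 75%
    retention is kept. ``retention`` needs columns subject, system,
    retention.
    """
    t = retention.copy()
    t["excluded"] = t["retention"] < threshold
    return RetentionReport(
        table=t,
        mean_retention=float(t.retention.mean()),
        min_retention=float(t.retention.min()),
        max_retention=float(t.retention.max()),
        n_excluded=int(t.excluded.sum()),
    )


def preprocess_recording(
    rec: Recording,
    seg_len_s: float = 1.0,
    amp_threshold_uv: float = 100.0,
    target_fs: float | None = 128.0,
) -> tuple[Recording, float]:
    """Filter, reject segments, and (if needed) downsample one recording."""
    clean = apply_filters(rec)
    clean, frac = reject_segments(clean, seg_len_s, amp_threshold_uv)
    if target_fs is not None and clean.fs != target_fs:
        clean = downsample(clean, target_fs)
    return clean, frac
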