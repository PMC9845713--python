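"""ECG-to-NN preprocessing: R-peak detection, artifact rules, epoching.

The study design analyses the earliest one-hour ECG epoch recorded before
12 h of age, split into five-minute segments with 50% overlap; segments more
than half covered by artifact are discarded. Manual beat editing is replaced
here by two automated rules (a physiologic range gate and a running-median
deviation gate), both configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks, hilbert

from .exceptions import (
    InsufficientDataError,
    InvalidSpecificationError,
    NoEpochError,
    NoPeaksDetectedError,
)
from .series import RRSeries

__all__ = [
    "ECGRecord",
    "Segment",
    "SegmentSet",
    "detect_rpeaks",
    "flag_artifacts",
    "segment_epoch",
    "select_earliest_epoch",
    "read_ecg_edf",
]


@dataclass
class ECGRecord:
    """Single-lead ECG: voltage samples, sampling rate, start age (hours)."""

    samples: np.ndarray
    fs_hz: float
    start_age_h: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise InvalidSpecificationError("fs_hz must be positive")


@dataclass
class Segment:
    start_s: float
    end_s: float
    indices: np.ndarray  # interval indices (into the parent RRSeries)
    artifact_fraction: float


@dataclass
class SegmentSet:
    """Retained five-minute segments of one epoch."""

    segments: list[Segment]
    removed_fraction: float  # fraction of epoch time covered by flagged beats
    n_total_segments: int = 0
    segment_length_s: float = 300.0

    def __len__(self) -> int:
        return len(self.segments)


def detect_rpeaks(ecg: ECGRecord, refractory_s: float = 0.2) -> RRSeries:
    """Detect R-peaks on a band-passed QRS envelope.

    The signal is band-passed at 5-30 Hz, its Hilbert envelope is peak-picked
    with a 200 ms refractory period, and peaks below an adaptive threshold
    (a fraction of a robust upper quantile of candidate heights) are
    discarded. The envelope is used rather than the rectified signal so a
    single noise sample cannot cancel a peak. Peaks within 250 ms of the
    record boundaries are dropped (filter edge effects). Spurious extra
    detections are tolerated here; downstream artifact screening removes
    the implausible intervals they create.
    """
    if ecg.fs_hz < 100:
        raise InvalidSpecificationError("R-peak detection requires fs_hz >= 100")
    x = ecg.samples
    if x.size < 2 * ecg.fs_hz:
        raise InsufficientDataError("record shorter than two seconds")
    if np.ptp(x) == 0:
        raise NoPeaksDetectedError("flat-line ECG")
    fs = ecg.fs_hz
    nyq = fs / 2.0
    b, a = butter(2, [5.0 / nyq, min(30.0, 0.9 * nyq) / nyq], btype="band")
    filt = filtfilt(b, a, x)
    env = np.abs(hilbert(filt))

    dist = max(1, int(round(refractory_s * fs)))
    cand, _ = find_peaks(env, distance=dist)
    if cand.size == 0:
        raise NoPeaksDetectedError("no candidate peaks")
    thr = 0.4 * np.quantile(env[cand], 0.9)
    peaks = cand[env[cand] > thr]
    edge = int(round(0.25 * fs))
    peaks = peaks[(peaks >= edge) & (peaks <= x.size - edge)]
    if peaks.size < 2:
        raise NoPeaksDetectedError("fewer than two R-peaks above threshold")
    times = peaks / fs
    intervals = np.diff(times) * 1000.0
    return RRSeries(times[1:], intervals, None, ecg.start_age_h)


def flag_artifacts(
    rr: RRSeries,
    lo_ms: float = 200.0,
    hi_ms: float = 1200.0,
    rel_tolerance: float = 0.3,
    window_beats: int = 11,
) -> RRSeries:
    """Flag beats whose interval leaves [lo, hi] ms or deviates from the
    centred running median by more than ``rel_tolerance`` of that median.

    Intervals are left unchanged; only the artifact mask is updated (OR-ed
    with any pre-existing flags).
    """
    if rr.n_beats < 10:
        raise InsufficientDataError("artifact screening requires >= 10 beats")
    x = pd.Series(rr.intervals_ms)
    med = x.rolling(window_beats, center=True, min_periods=1).median().to_numpy()
    out_of_range = (rr.intervals_ms < lo_ms) | (rr.intervals_ms > hi_ms)
    deviant = np.abs(rr.intervals_ms - med) > rel_tolerance * med
    return rr.with_mask(rr.artifact_mask | out_of_range | deviant)


def _flagged_time_in_window(rr: RRSeries, start: float, end: float) -> float:
    """Total time (s) inside [start, end] covered by flagged intervals."""
    t1 = rr.beat_times_s
    t0 = t1 - rr.intervals_ms / 1000.0
    lo = np.clip(t0, start, end)
    hi = np.clip(t1, start, end)
    return float(np.sum((hi - lo)[rr.artifact_mask]))


def segment_epoch(
    rr: RRSeries,
    segment_length_s: float = 300.0,
    step_s: float = 150.0,
    max_artifact_fraction: float = 0.5,
) -> SegmentSet:
    """Tile the epoch into overlapping segments and drop artifact-heavy ones.

    Segments start every ``step_s`` seconds from the epoch start; a segment
    is dropped when the time covered by flagged beats exceeds
    ``max_artifact_fraction`` of its length. ``removed_fraction`` reports the
    flagged share of the whole epoch.
    """
    if rr.n_beats == 0 or rr.duration_s < segment_length_s:
        raise InsufficientDataError(
            f"epoch covers {rr.duration_s:.1f} s, need >= {segment_length_s} s"
        )
    origin = rr.epoch_start_s
    n_seg = int(np.floor((rr.duration_s - segment_length_s) / step_s)) + 1
    segments: list[Segment] = []
    for k in range(n_seg):
        start = origin + k * step_s
        end = start + segment_length_s
        sel = (rr.beat_times_s > start) & (rr.beat_times_s <= end)
        frac = _flagged_time_in_window(rr, start, end) / segment_length_s
        if frac <= max_artifact_fraction:
            segments.append(Segment(start, end, np.flatnonzero(sel), frac))
    removed = _flagged_time_in_window(rr, origin, origin + rr.duration_s)
    return SegmentSet(
        segments=segments,
        removed_fraction=removed / rr.duration_s,
        n_total_segments=n_seg,
        segment_length_s=segment_length_s,
    )


def select_earliest_epoch(
    rr: RRSeries,
    max_age_h: float = 12.0,
    duration_s: float = 3600.0,
    min_usable_fraction: float | None = None,
) -> RRSeries:
    """Crop the earliest window of ``duration_s`` ending before ``max_age_h``.

    Candidate starts are the record start and each beat time. When
    ``min_usable_fraction`` is set, a window is admissible only if at least
    that fraction of its span is covered by unflagged beats; the start then
    shifts forward to the first admissible window.
    """
    if rr.n_beats == 0:
        raise NoEpochError("empty record")
    if rr.start_age_h * 3600.0 + duration_s > max_age_h * 3600.0 + 1e-9:
        raise NoEpochError(
            f"record starts at {rr.start_age_h:.2f} h; no {duration_s/3600:.2f} h "
            f"window fits before {max_age_h} h of age"
        )
    origin = rr.epoch_start_s
    record_end = rr.beat_times_s[-1]
    latest_start = min(
        record_end - duration_s,
        (max_age_h - rr.start_age_h) * 3600.0 - duration_s + origin,
    )
    if latest_start < origin - 1e-9:
        raise NoEpochError("record too short for the requested epoch duration")

    candidates = np.concatenate([[origin], rr.beat_times_s])
    candidates = candidates[candidates <= latest_start + 1e-9]

    t1 = rr.beat_times_s
    t0 = t1 - rr.intervals_ms / 1000.0
    for start in candidates:
        end = start + duration_s
        if min_usable_fraction is not None:
            lo = np.clip(t0, start, end)
            hi = np.clip(t1, start, end)
            usable = float(np.sum((hi - lo)[~rr.artifact_mask]))
            if usable / duration_s < min_usable_fraction:
                continue
        sel = (t1 > start) & (t1 <= end)
        if not sel.any():
            continue
        return RRSeries(
            t1[sel] - start,
            rr.intervals_ms[sel],
            rr.artifact_mask[sel],
            rr.start_age_h + start / 3600.0,
        )
    raise NoEpochError("no admissible epoch satisfies the usability requirement")


def read_ecg_edf(path: str, channel: str | int = 0, start_age_h: float = 0.0) -> ECGRecord:
    """Load one ECG channel from an EDF file (requires the optional ``mne``
    dependency); plain numeric series can instead be wrapped directly in
    :class:`ECGRecord`."""
    try:
        import mne  # type: ignore
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    name = raw.ch_names[channel] if isinstance(channel, int) else channel
    data = raw.get_data(picks=[name])[0]
    return ECGRecord(data, float(raw.info["sfreq"]), start_age_h)
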