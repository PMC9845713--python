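"""Per-segment HRV features and their epoch-level summary.

Eleven features are computed on each retained five-minute segment (time
domain: mean NN, SDNN, TINN; frequency domain: VLF/LF/HF power and LF/HF
ratio; complexity: four summaries of the multiscale-entropy curve) and each
is summarised over segments by its median, ignoring segments where a feature
is undefined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .entropy import MSEConfig, mse_curve, mse_features
from .exceptions import InsufficientDataError
from .preprocess import SegmentSet
from .series import RRSeries
from .spectral import SpectralBands, band_powers

__all__ = [
    "HRVFeatureSet",
    "FEATURE_COLUMNS",
    "time_domain",
    "tinn",
    "extract_all",
    "extract_cohort",
]

TINN_BIN_MS = 1000.0 / 128.0  # 7.8125 ms histogram bin, HRV Task Force convention

FEATURE_COLUMNS = [
    "mean_nn_ms",
    "sdnn_ms",
    "tinn_ms",
    "vlf_power_ms2",
    "lf_power_ms2",
    "hf_power_ms2",
    "lf_hf_ratio",
    "mse_complexity_index",
    "mse_max",
    "mse_short_slope",
    "mse_long_slope",
]


@dataclass
class HRVFeatureSet:
    """Median-over-segments HRV features for one subject epoch."""

    mean_nn_ms: float
    sdnn_ms: float
    tinn_ms: float
    vlf_power_ms2: float
    lf_power_ms2: float
    hf_power_ms2: float
    lf_hf_ratio: float
    mse_complexity_index: float
    mse_max: float
    mse_short_slope: float
    mse_long_slope: float
    removed_fraction: float = 0.0
    n_segments: int = 0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def tinn(nn_ms: np.ndarray, bin_width_ms: float = TINN_BIN_MS) -> float:
    """Triangular interpolation of the NN histogram: base width (ms) of the
    best least-squares triangle fitted to the interval histogram.

    The histogram uses fixed-width bins aligned to multiples of the bin
    width; the triangle apex is pinned at the modal bin centre with the
    modal height, and all (left edge, right edge) pairs are searched
    exhaustively.
    """
    x = np.asarray(nn_ms, dtype=float)
    lo = math.floor(x.min() / bin_width_ms) * bin_width_ms
    hi = math.ceil(x.max() / bin_width_ms) * bin_width_ms
    if hi <= lo:
        hi = lo + bin_width_ms
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    counts, _ = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    k = int(np.argmax(counts))
    apex_x, apex_h = centers[k], float(counts[k])

    best_err, best_width = math.inf, bin_width_ms
    for i in range(k + 1):  # left base point: a left bin edge at or before apex
        n_edge = edges[i]
        for j in range(k + 1, len(edges)):  # right base point after apex
            m_edge = edges[j]
            tri = np.zeros_like(centers)
            left = (centers > n_edge) & (centers <= apex_x)
            right = (centers > apex_x) & (centers < m_edge)
            tri[left] = apex_h * (centers[left] - n_edge) / (apex_x - n_edge)
            tri[right] = apex_h * (m_edge - centers[right]) / (m_edge - apex_x)
            err = float(np.sum((counts - tri) ** 2))
            if err < best_err - 1e-12:
                best_err, best_width = err, m_edge - n_edge
    return best_width


def time_domain(nn_ms: np.ndarray) -> dict[str, float]:
    """Mean NN, SDNN (sample SD) and TINN of one segment, all in ms."""
    x = np.asarray(nn_ms, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("time-domain features require >= 2 intervals")
    return {
        "mean_nn_ms": float(x.mean()),
        "sdnn_ms": float(x.std(ddof=1)),
        "tinn_ms": tinn(x),
    }


def segment_features(
    times_s: np.ndarray,
    nn_ms: np.ndarray,
    bands: SpectralBands | None = None,
    mse_cfg: MSEConfig | None = None,
) -> dict[str, float]:
    """All eleven features for one segment's unflagged beats."""
    feats = time_domain(nn_ms)
    feats.update(band_powers(times_s, nn_ms, bands))
    try:
        feats.update(mse_features(mse_curve(nn_ms, mse_cfg), mse_cfg))
    except InsufficientDataError:
        feats.update(
            dict.fromkeys(
                ("mse_complexity_index", "mse_max", "mse_short_slope", "mse_long_slope"),
                math.nan,
            )
        )
    return feats


def extract_all(
    rr: RRSeries,
    segments: SegmentSet,
    bands: SpectralBands | None = None,
    mse_cfg: MSEConfig | None = None,
) -> HRVFeatureSet:
    """Per-segment features on unflagged beats, summarised by the median.

    The LF/HF ratio is the median of per-segment ratios, not the ratio of
    median powers. Segments where a feature is undefined are ignored for
    that feature's median.
    """
    if len(segments) == 0:
        raise InsufficientDataError("no retained segments")
    rows = []
    for seg in segments.segments:
        idx = seg.indices[~rr.artifact_mask[seg.indices]]
        if idx.size < 4:
            continue
        rows.append(segment_features(rr.beat_times_s[idx], rr.intervals_ms[idx], bands, mse_cfg))
    if not rows:
        raise InsufficientDataError("no segment has enough unflagged beats")
    table = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN feature columns
        med = table.median(skipna=True)
    return HRVFeatureSet(
        **{c: float(med.get(c, math.nan)) for c in FEATURE_COLUMNS},
        removed_fraction=segments.removed_fraction,
        n_segments=len(segments),
    )


def extract_cohort(
    rr_map: dict[str, RRSeries],
    bands: SpectralBands | None = None,
    mse_cfg: MSEConfig | None = None,
    flag_kwargs: dict | None = None,
    max_artifact_fraction: float = 0.5,
) -> pd.DataFrame:
    """Run artifact screening, segmentation and feature extraction for a
    whole cohort; returns one row per subject indexed by subject id."""
    from .preprocess import flag_artifacts, segment_epoch

    rows = {}
    for sid, rr in rr_map.items():
        flagged = flag_artifacts(rr, **(flag_kwargs or {}))
        segs = segment_epoch(flagged, max_artifact_fraction=max_artifact_fraction)
        rows[sid] = extract_all(flagged, segs, bands, mse_cfg).as_dict()
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out
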