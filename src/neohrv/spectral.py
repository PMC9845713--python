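"""Frequency-domain HRV: tachogram resampling and band powers.

The neonatal band preset places HF at 0.2-2 Hz because newborn respiratory
rates reach ~2 Hz; the adult Task-Force preset (LF 0.04-0.15, HF 0.15-0.4 Hz)
is available for comparison. Powers are reported in ms^2 as the integral of a
Welch PSD of the evenly resampled, mean-subtracted tachogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .exceptions import ConfigurationError, InsufficientDataError

__all__ = ["SpectralBands", "resample_tachogram", "band_powers"]


@dataclass
class SpectralBands:
    """Band edges (Hz), resampling rate and PSD estimator settings."""

    vlf: tuple[float, float] = (0.01, 0.04)
    lf: tuple[float, float] = (0.04, 0.2)
    hf: tuple[float, float] = (0.2, 2.0)
    resample_hz: float = 4.0
    psd_method: str = "welch"
    welch_window_s: float = 120.0

    def __post_init__(self) -> None:
        edges = [*self.vlf, *self.lf, *self.hf]
        if any(e <= 0 for e in edges) or any(
            b <= a for a, b in (self.vlf, self.lf, self.hf)
        ):
            raise ConfigurationError("band edges must be positive and increasing")
        if not (self.vlf[1] == self.lf[0] and self.lf[1] == self.hf[0]):
            raise ConfigurationError("bands must be contiguous (VLF|LF|HF)")
        if self.resample_hz < 2 * self.hf[1]:
            raise ConfigurationError(
                f"resample_hz={self.resample_hz} must be at least twice the HF "
                f"upper edge ({self.hf[1]} Hz); the HF band may extend to Nyquist"
            )
        if self.psd_method != "welch":
            raise ConfigurationError(f"unknown psd_method {self.psd_method!r}")

    @classmethod
    def neonatal(cls) -> "SpectralBands":
        return cls()

    @classmethod
    def task_force(cls) -> "SpectralBands":
        """Adult short-term preset (VLF 0.0033-0.04, LF 0.04-0.15, HF 0.15-0.4)."""
        return cls(vlf=(0.0033, 0.04), lf=(0.04, 0.15), hf=(0.15, 0.4))


def resample_tachogram(
    beat_times_s: np.ndarray,
    intervals_ms: np.ndarray,
    resample_hz: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline interpolation of the interval series onto a uniform grid.

    Returns ``(grid_times_s, intervals_ms_on_grid)``.
    """
    t = np.asarray(beat_times_s, dtype=float)
    x = np.asarray(intervals_ms, dtype=float)
    if t.size < 4:
        raise InsufficientDataError("need at least 4 beats to build a tachogram")
    n = int(np.floor((t[-1] - t[0]) * resample_hz)) + 1
    grid = t[0] + np.arange(n) / resample_hz
    return grid, CubicSpline(t, x)(grid)


def band_powers(
    beat_times_s: np.ndarray,
    intervals_ms: np.ndarray,
    bands: SpectralBands | None = None,
) -> dict[str, float]:
    """VLF/LF/HF powers (ms^2) and the LF/HF ratio for one segment.

    The tachogram is mean-subtracted before the Welch estimate (Hann window,
    ``welch_window_s`` segments, 50% overlap) and each band power is the
    trapezoidal integral of the PSD between the band edges.
    """
    bands = bands or SpectralBands()
    grid, x = resample_tachogram(beat_times_s, intervals_ms, bands.resample_hz)
    x = x - x.mean()
    nper = min(x.size, int(round(bands.welch_window_s * bands.resample_hz)))
    f, psd = welch(
        x,
        fs=bands.resample_hz,
        window="hann",
        nperseg=nper,
        noverlap=nper // 2,
        detrend="constant",
    )

    def integrate(lo: float, hi: float) -> float:
        sel = (f >= lo) & (f <= hi)
        if sel.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[sel], f[sel]))

    vlf = integrate(*bands.vlf)
    lf = integrate(*bands.lf)
    hf = integrate(*bands.hf)
    ratio = lf / hf if hf > 0 else float("inf") if lf > 0 else float("nan")
    return {
        "vlf_power_ms2": vlf,
        "lf_power_ms2": lf,
        "hf_power_ms2": hf,
        "lf_hf_ratio": ratio,
    }
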