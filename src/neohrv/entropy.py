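"""Sample entropy and multiscale entropy (MSE) of interbeat series.

Sample entropy follows the Richman-Moorman template-counting definition:
with ``N - m`` templates of length ``m`` (the trailing template is dropped so
the same count of templates is used at both lengths), ``B`` counts ordered
pairs ``i < j`` whose templates match within Chebyshev tolerance ``r`` and
``A`` counts the subset that still match when extended by one point.
SampEn = -ln(A/B), in nats; self-matches are excluded by construction.

The MSE curve smooths the series with a moving-average filter of width equal
to the scale factor (no decimation) and re-estimates sample entropy at each
scale with the tolerance held fixed at ``r_factor`` times the SD of the
scale-1 series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InsufficientDataError

__all__ = ["MSEConfig", "sample_entropy", "sampen_counts", "mse_curve", "mse_features"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _sampen_counts_py(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Vectorised pair counting; same arithmetic as the jitted kernel."""
    n = x.size
    nt = n - m
    win = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    nxt = x[m:]
    a = b = 0
    for i in range(nt - 1):
        d = np.max(np.abs(win[i + 1 :] - win[i]), axis=1)
        hit = d <= r
        b += int(hit.sum())
        a += int((hit & (np.abs(nxt[i + 1 :] - nxt[i]) <= r)).sum())
    return a, b


if _HAVE_NUMBA:

    @njit(cache=True)
    def _sampen_counts_nb(x, m, r):  # pragma: no cover - compiled
        n = x.shape[0]
        nt = n - m
        a = 0
        b = 0
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                ok = True
                for k in range(m):
                    d = abs(x[i + k] - x[j + k])
                    if d > r:
                        ok = False
                        break
                if ok:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b


def sampen_counts(series: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Return the (A, B) template-match pair counts used by sample entropy."""
    x = np.ascontiguousarray(series, dtype=float)
    if x.size < m + 2:
        raise InsufficientDataError(f"need at least {m + 2} points, got {x.size}")
    if _HAVE_NUMBA:
        a, b = _sampen_counts_nb(x, m, r)
        return int(a), int(b)
    return _sampen_counts_py(x, m, r)


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy (nats) with embedding dimension ``m`` and absolute
    tolerance ``r``; returns NaN when the estimate is undefined (A or B = 0).
    """
    if r is None or r <= 0:
        raise ConfigurationError("tolerance r must be positive")
    if m < 1:
        raise ConfigurationError("embedding dimension m must be >= 1")
    a, b = sampen_counts(series, m, r)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


@dataclass
class MSEConfig:
    """Multiscale-entropy settings.

    ``r_factor`` is multiplied by the sample SD of the scale-1 series and the
    resulting absolute tolerance is reused at every scale (the usual MSE
    convention); set ``r_per_scale`` to re-derive the tolerance per scale.
    ``coarse_grain`` selects plain moving-average smoothing (default) or a
    decimating variant that keeps every ``tau``-th smoothed point.
    """

    m: int = 2
    r_factor: float = 0.15
    max_scale: int = 20
    short_scale_range: tuple[int, int] = (1, 5)
    long_scale_range: tuple[int, int] = (6, 20)
    coarse_grain: str = "moving_average"  # or "decimate"
    r_per_scale: bool = False
    min_points_at_max_scale: int = 50

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if not 0 < self.r_factor < 1:
            raise ConfigurationError("r_factor must be in (0, 1)")
        if self.max_scale < self.long_scale_range[1]:
            raise ConfigurationError("max_scale must cover the long-scale range")
        if self.coarse_grain not in ("moving_average", "decimate"):
            raise ConfigurationError(f"unknown coarse_grain {self.coarse_grain!r}")

    @property
    def scales(self) -> np.ndarray:
        return np.arange(1, self.max_scale + 1)


def _coarse_grain(x: np.ndarray, tau: int, mode: str) -> np.ndarray:
    if tau == 1:
        return x
    sm = np.convolve(x, np.full(tau, 1.0 / tau), mode="valid")
    if mode == "decimate":
        sm = sm[::tau]
    return sm


def mse_curve(series: np.ndarray, cfg: MSEConfig | None = None) -> np.ndarray:
    """Entropy at scales ``1..max_scale``; NaN entries where undefined."""
    cfg = cfg or MSEConfig()
    x = np.asarray(series, dtype=float)
    if x.size - cfg.max_scale + 1 < cfg.min_points_at_max_scale:
        raise InsufficientDataError(
            f"series of {x.size} points leaves fewer than "
            f"{cfg.min_points_at_max_scale} points at scale {cfg.max_scale}"
        )
    sd = float(np.std(x, ddof=1))
    curve = np.empty(cfg.max_scale)
    for tau in cfg.scales:
        y = _coarse_grain(x, int(tau), cfg.coarse_grain)
        r = cfg.r_factor * (float(np.std(y, ddof=1)) if cfg.r_per_scale else sd)
        if r == 0.0:
            # constant series: every template matches at both lengths
            curve[tau - 1] = 0.0
            continue
        curve[tau - 1] = sample_entropy(y, cfg.m, r)
    return curve


def _slope(scales: np.ndarray, values: np.ndarray) -> float:
    if np.any(~np.isfinite(values)):
        return math.nan
    return float(np.polyfit(scales, values, 1)[0])


def mse_features(curve: np.ndarray, cfg: MSEConfig | None = None) -> dict[str, float]:
    """Summary features of an MSE curve.

    complexity index = trapezoidal area under the curve over all scales;
    maximum = max entropy; short/long slopes = least-squares line slopes
    over the configured scale ranges. A feature whose required scales
    contain an undefined entropy is returned as NaN.
    """
    cfg = cfg or MSEConfig()
    curve = np.asarray(curve, dtype=float)
    scales = cfg.scales.astype(float)
    if curve.size != scales.size:
        raise ConfigurationError("curve length does not match configured scales")
    finite = np.isfinite(curve)
    ci = float(np.trapezoid(curve, scales)) if finite.all() else math.nan
    mx = float(np.max(curve)) if finite.all() else math.nan
    s_lo, s_hi = cfg.short_scale_range
    l_lo, l_hi = cfg.long_scale_range
    short = _slope(scales[s_lo - 1 : s_hi], curve[s_lo - 1 : s_hi])
    long_ = _slope(scales[l_lo - 1 : l_hi], curve[l_lo - 1 : l_hi])
    return {
        "mse_complexity_index": ci,
        "mse_max": mx,
        "mse_short_slope": short,
        "mse_long_slope": long_,
    }
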