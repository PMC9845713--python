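"""Core interbeat-interval container and plain-text readers/writers.

An RR series is stored beat-wise: ``intervals_ms[i]`` is the interval that
*ends* at ``beat_times_s[i]``, so ``beat_times_s`` excludes the very first
R-peak of a record. A per-beat boolean ``artifact_mask`` marks intervals that
artifact screening (or the synthetic ground truth) considers corrupted;
flagged beats keep their raw values and are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import InvalidSpecificationError

__all__ = ["RRSeries", "read_rr_table", "write_rr_table"]


@dataclass
class RRSeries:
    """Timestamped NN/RR intervals with an artifact mask.

    Parameters
    ----------
    beat_times_s
        Strictly increasing beat timestamps in seconds, relative to the
        start of the record.
    intervals_ms
        Interval preceding each beat, milliseconds, strictly positive.
    artifact_mask
        Boolean mask, same length; ``True`` marks a corrupted beat.
    start_age_h
        Postnatal age (hours) at the start of the record.
    """

    beat_times_s: np.ndarray
    intervals_ms: np.ndarray
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    start_age_h: float = 0.0

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.intervals_ms.shape, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.beat_times_s.ndim != 1:
            raise InvalidSpecificationError("beat_times_s must be 1-D")
        if self.beat_times_s.shape != self.intervals_ms.shape:
            raise InvalidSpecificationError("beat times and intervals differ in length")
        if self.artifact_mask.shape != self.intervals_ms.shape:
            raise InvalidSpecificationError("artifact mask length mismatch")
        if self.beat_times_s.size:
            if np.any(np.diff(self.beat_times_s) <= 0):
                raise InvalidSpecificationError("beat times must be strictly increasing")
            if np.any(self.intervals_ms <= 0):
                raise InvalidSpecificationError("intervals must be positive")

    @property
    def n_beats(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def epoch_start_s(self) -> float:
        """Start of the covered epoch: first beat time minus its interval."""
        return float(self.beat_times_s[0] - self.intervals_ms[0] / 1000.0)

    @property
    def duration_s(self) -> float:
        """Time covered by the intervals, seconds."""
        if not self.n_beats:
            return 0.0
        return float(self.beat_times_s[-1] - self.epoch_start_s)

    def clean(self) -> "RRSeries":
        """Return a copy restricted to unflagged beats."""
        keep = ~self.artifact_mask
        return RRSeries(
            self.beat_times_s[keep],
            self.intervals_ms[keep],
            np.zeros(int(keep.sum()), dtype=bool),
            self.start_age_h,
        )

    def with_mask(self, mask: np.ndarray) -> "RRSeries":
        return replace(self, artifact_mask=np.asarray(mask, dtype=bool))


def write_rr_table(rr: RRSeries, path: str | Path) -> None:
    """Write a two-column text table (beat time s, interval ms).

    The artifact mask is stored as a third 0/1 column; the start age is
    recorded in a comment header so round-trips are lossless.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# start_age_h={rr.start_age_h:.6f}\n")
        fh.write("time_s\tinterval_ms\tartifact\n")
        for t, x, a in zip(rr.beat_times_s, rr.intervals_ms, rr.artifact_mask):
            fh.write(f"{t:.6f}\t{x:.6f}\t{int(a)}\n")


def read_rr_table(path: str | Path) -> RRSeries:
    """Read a two- or three-column RR text table written by this package
    (or any whitespace/tab-delimited time/interval file)."""
    path = Path(path)
    start_age_h = 0.0
    rows: list[tuple[float, float, bool]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "start_age_h=" in line:
                    start_age_h = float(line.split("start_age_h=")[1])
                continue
            parts = line.replace(",", "\t").split()
            try:
                t, x = float(parts[0]), float(parts[1])
            except ValueError:
                continue  # header line
            a = bool(int(float(parts[2]))) if len(parts) > 2 else False
            rows.append((t, x, a))
    if not rows:
        raise InvalidSpecificationError(f"no RR rows found in {path}")
    t, x, a = zip(*rows)
    return RRSeries(np.array(t), np.array(x), np.array(a, dtype=bool), start_age_h)
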