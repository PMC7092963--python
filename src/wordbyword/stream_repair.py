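"""Packet-loss detection and marker-to-sample alignment for wireless EEG.

Bluetooth transport can drop runs of samples.  Because every sample
carries a session-clock timestamp, a gap shows up as a timestamp delta
exceeding the nominal sampling period; epochs must then be cut at
sample indices found from the timestamps, not from naive
``(time - t0) * rate`` arithmetic.  Lost samples are never
reconstructed — downstream epochs that overlap a gap are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import EEGRecording


@dataclass(frozen=True)
class Gap:
    last_sample_before: int   # index of the final sample preceding the gap
    n_lost: int               # samples missing
    start_s: float            # session time of the first lost sample
    duration_s: float


@dataclass
class GapList:
    gaps: list
    nominal_rate: float = 500.0

    def __post_init__(self):
        idx = [g.last_sample_before for g in self.gaps]
        if sorted(idx) != idx:
            raise ValueError("gaps must be sorted")
        if any(g.n_lost < 1 for g in self.gaps):
            raise ValueError("each gap must lose at least one sample")

    @property
    def total_lost(self) -> int:
        return sum(g.n_lost for g in self.gaps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([g.__dict__ for g in self.gaps])


def detect_gaps(
    timestamps: np.ndarray, nominal_rate: float = 500.0, tol: float = 0.5
) -> GapList:
    """Find dropped-sample runs from per-sample timestamps.

    A delta above ``(1 + tol)`` nominal periods is a gap of
    ``round(delta * rate) - 1`` lost samples.  Timestamps must be
    non-decreasing.
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.size and np.any(np.diff(ts) < 0):
        raise ValueError("timestamps must be non-decreasing")
    period = 1.0 / nominal_rate
    deltas = np.diff(ts)
    where = np.flatnonzero(deltas > (1.0 + tol) * period)
    gaps = []
    for i in where:
        n_lost = int(round(deltas[i] * nominal_rate)) - 1
        if n_lost >= 1:
            gaps.append(
                Gap(
                    last_sample_before=int(i),
                    n_lost=n_lost,
                    start_s=float(ts[i] + period),
                    duration_s=n_lost * period,
                )
            )
    return GapList(gaps=gaps, nominal_rate=nominal_rate)


@dataclass(frozen=True)
class AlignedMarker:
    time_s: float
    sample_index: int
    in_gap: bool


def align_markers(
    marker_times, timestamps: np.ndarray, gaps: GapList | None = None
) -> list[AlignedMarker]:
    """Map session-time markers to sample indices of a gappy stream.

    Each marker maps to the sample whose timestamp is nearest; a marker
    falling inside a lost run maps to the first post-gap sample and is
    flagged, so downstream epoching can drop it.
    """
    ts = np.asarray(timestamps, dtype=float)
    if gaps is None:
        gaps = detect_gaps(ts)
    period = 1.0 / gaps.nominal_rate
    out = []
    for t in np.atleast_1d(np.asarray(marker_times, dtype=float)):
        if t < ts[0] - 0.5 * period or t > ts[-1] + 0.5 * period:
            raise ValueError(f"marker at {t:.4f}s outside stream span")
        i = int(np.searchsorted(ts, t))
        if i == 0:
            j = 0
        elif i >= ts.size:
            j = ts.size - 1
        else:
            j = i if (ts[i] - t) <= (t - ts[i - 1]) else i - 1
        in_gap = abs(ts[j] - t) > 0.5 * period + 1e-9
        if in_gap:
            j = int(np.searchsorted(ts, t))  # first post-gap sample
            j = min(j, ts.size - 1)
        out.append(AlignedMarker(time_s=float(t), sample_index=j, in_gap=bool(in_gap)))
    return out


def repair_report(recording: EEGRecording, tol: float = 0.5) -> pd.DataFrame:
    """Gap table of one recording (empty if the stream is regular)."""
    return detect_gaps(recording.timestamps, recording.rate, tol).to_frame()
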