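"""EEG preprocessing, epoching, artifact handling and condition balancing.

The preprocessing chain for each participant's stream mirrors standard
ERP practice for this paradigm: 0.1-30 Hz zero-phase Hann-window FIR
bandpass, bad-channel detection (flat or decorrelated channels),
burst cleaning in a principal-component subspace learned from clean
calibration data, re-referencing to averaged mastoids (TP9/TP10),
spherical-spline interpolation of removed channels, epoching from
-500 to 1500 ms around events with -100..0 ms baseline correction,
a one-pass 3-SD amplitude criterion for epoch rejection, and seeded
subsampling so compared conditions enter statistics with equal counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import eval_legendre

from .montage import CHANNELS, MASTOIDS, position_matrix
from .recording import EEGRecording
from .stream_repair import GapList, align_markers, detect_gaps
from ._utils import ms_to_samples

# ----------------------------------------------------------------------
# filtering


def bandpass(
    recording: EEGRecording, low: float = 0.1, high: float = 30.0
) -> EEGRecording:
    """Zero-phase Hann-window FIR bandpass (-6 dB at the cutoffs).

    The kernel is linear-phase and applied centered, so the group delay
    cancels; transition widths follow the common "half the low cutoff /
    a quarter of the high cutoff" rule.
    """
    rate = recording.rate
    if not (0 < low < high < rate / 2):
        raise ValueError(f"invalid band ({low}, {high}) at rate {rate}")
    trans_lo = max(low * 0.5, 0.05)
    n_taps = int(np.ceil(3.3 * rate / trans_lo))
    n_taps += (n_taps + 1) % 2  # odd length
    taps = signal.firwin(
        n_taps, [low, high], fs=rate, pass_zero=False, window="hann"
    )
    data = signal.oaconvolve(
        recording.data.astype(np.float64), taps[None, :], mode="same", axes=1
    )
    return recording.copy_with(data=data.astype(recording.data.dtype))


# ----------------------------------------------------------------------
# bad channels


def detect_bad_channels(
    recording: EEGRecording,
    flat_uv: float = 1e-3,
    corr_threshold: float = 0.4,
    min_duration_s: float = 60.0,
) -> list[str]:
    """Channels that are flat or decorrelated from their robust neighbor
    prediction (deterministic)."""
    if recording.duration < min_duration_s:
        raise ValueError(
            f"need >= {min_duration_s:.0f} s of data, got {recording.duration:.1f} s"
        )
    X = recording.data.astype(np.float64)
    bad = set()
    sd = X.std(axis=1)
    for i, ch in enumerate(recording.channels):
        if sd[i] < flat_uv:
            bad.add(ch)
    # neighbor prediction: median of the spatially nearest channels
    pos = position_matrix(recording.channels)
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    for i, ch in enumerate(recording.channels):
        if ch in bad:
            continue
        order = np.argsort(d2[i])
        neighbors = [j for j in order[1:7] if recording.channels[j] not in bad]
        pred = np.median(X[neighbors], axis=0)
        denom = X[i].std() * pred.std()
        r = float(np.dot(X[i] - X[i].mean(), pred - pred.mean()) / (X[i].size * denom + 1e-24))
        if r < corr_threshold:
            bad.add(ch)
    return [c for c in recording.channels if c in bad]


def drop_channels(recording: EEGRecording, channels: list[str]) -> EEGRecording:
    keep = [i for i, c in enumerate(recording.channels) if c not in channels]
    return EEGRecording(
        data=recording.data[keep],
        rate=recording.rate,
        channels=tuple(recording.channels[i] for i in keep),
        timestamps=recording.timestamps,
        participant=recording.participant,
    )


# ----------------------------------------------------------------------
# burst cleaning (simplified artifact-subspace reconstruction)


@dataclass
class BurstCalibration:
    mixing: np.ndarray        # eigenvectors (channels x components)
    comp_rms_mean: np.ndarray
    comp_rms_sd: np.ndarray
    window_s: float


def calibrate_bursts(
    calibration: np.ndarray, rate: float, window_s: float = 0.5
) -> BurstCalibration:
    """Learn the clean-data component subspace and per-component window
    statistics from an artifact-light calibration segment."""
    X = np.asarray(calibration, dtype=np.float64)
    n = int(window_s * rate)
    if X.shape[1] < 2 * n:
        raise ValueError("calibration shorter than two cleaning windows")
    X = X - X.mean(axis=1, keepdims=True)
    cov = X @ X.T / X.shape[1]
    _, vecs = np.linalg.eigh(cov)
    comps = vecs.T @ X
    starts = np.arange(0, X.shape[1] - n + 1, n // 2)
    rms = np.stack([np.sqrt(np.mean(comps[:, s : s + n] ** 2, axis=1)) for s in starts])
    med = np.median(rms, axis=0)
    mad = np.median(np.abs(rms - med), axis=0) * 1.4826
    return BurstCalibration(
        mixing=vecs, comp_rms_mean=med, comp_rms_sd=np.maximum(mad, 1e-12),
        window_s=window_s,
    )


def clean_bursts(
    recording: EEGRecording,
    calibration: np.ndarray | BurstCalibration,
    cutoff_k: float = 12.0,
    floor_mult: float = 3.0,
) -> EEGRecording:
    """Reconstruct burst-dominated windows in the calibration subspace.

    Sliding half-overlapping windows are projected onto the calibration
    eigenbasis; a component is deviant in a window when its RMS exceeds
    ``median + k MAD`` of the calibration statistics AND ``floor_mult``
    times the calibration median (the absolute floor keeps the cleaner
    targeted at burst artifacts an order of magnitude above background —
    ocular and motion transients — rather than event-locked activity in
    low-variance directions).  Deviant directions are projected out
    (their calibration-basis prediction from the retained components is
    zero, since the basis decorrelates the calibration data); cleaned
    windows are cross-faded, and windows with no deviant component pass
    through unchanged.
    """
    if not isinstance(calibration, BurstCalibration):
        calibration = calibrate_bursts(np.asarray(calibration), recording.rate)
    V = calibration.mixing
    X = recording.data.astype(np.float64)
    n = int(calibration.window_s * recording.rate)
    hop = n // 2
    out = X.copy()
    win = np.hanning(n)
    thresh = np.maximum(
        calibration.comp_rms_mean + cutoff_k * calibration.comp_rms_sd,
        floor_mult * calibration.comp_rms_mean,
    )
    first = True
    for s in range(0, X.shape[1] - n + 1, hop):
        seg = X[:, s : s + n]
        comps = V.T @ seg
        rms = np.sqrt(np.mean(comps**2, axis=1))
        deviant = rms > thresh
        if not deviant.any():
            continue
        comps[deviant] = 0.0
        rec = V @ comps
        if first:
            out[:, s : s + n] = rec
            first = False
        else:
            out[:, s : s + n] = out[:, s : s + n] * (1 - win)[None, :] + rec * win[None, :]
    return recording.copy_with(data=out.astype(recording.data.dtype))


# ----------------------------------------------------------------------
# reference and interpolation


def rereference(
    recording: EEGRecording, refs: tuple[str, str] = MASTOIDS
) -> EEGRecording:
    """Subtract the averaged-mastoid (TP9/TP10) signal from every channel."""
    idx = [recording.index_of(r) for r in refs]
    ref = recording.data[idx].mean(axis=0)
    return recording.copy_with(data=recording.data - ref[None, :])


def _spline_g(cosang: np.ndarray, order: int = 4, n_terms: int = 30) -> np.ndarray:
    """Spherical-spline kernel g(cos) with order-m smoothing."""
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n**order * (n + 1) ** order)
    P = np.stack([eval_legendre(k, cosang) for k in n])
    return np.tensordot(coef, P, axes=(0, 0)) / (4 * np.pi)


def interpolation_matrix(
    good_pos: np.ndarray, bad_pos: np.ndarray, order: int = 4, reg: float = 1e-5
) -> np.ndarray:
    """Spherical-spline operator mapping good-channel data to bad sites."""
    G = _spline_g(np.clip(good_pos @ good_pos.T, -1, 1), order)
    G = G + reg * np.eye(len(good_pos))
    Gb = _spline_g(np.clip(bad_pos @ good_pos.T, -1, 1), order)
    n_good = len(good_pos)
    # solve with the constant (c0) term: [[G, 1],[1^T, 0]] [c; c0] = [x; 0]
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0
    Ainv = np.linalg.pinv(A)
    # data -> coefficients -> bad-site values
    B = np.concatenate([Gb, np.ones((len(bad_pos), 1))], axis=1)
    return B @ Ainv[:, :n_good]


def interpolate_channels(
    recording: EEGRecording,
    missing: list[str],
    full_channels: tuple[str, ...] = CHANNELS,
) -> EEGRecording:
    """Rebuild missing channels by order-4 spherical-spline interpolation.

    ``recording`` holds the good channels; the result carries
    ``full_channels`` in canonical order with the missing ones
    reconstructed from the good-channel topography.
    """
    if not missing:
        return recording.copy_with()
    good = [c for c in full_channels if c in recording.channels]
    if len(good) < 4:
        raise ValueError("need at least 4 good channels for spherical splines")
    unknown = [c for c in missing if c not in full_channels]
    if unknown:
        raise ValueError(f"missing channels not in montage: {unknown}")
    M = interpolation_matrix(position_matrix(tuple(good)), position_matrix(tuple(missing)))
    bad_data = M @ recording.data[[recording.index_of(c) for c in good]].astype(np.float64)
    data = np.empty((len(full_channels), recording.n_samples), dtype=np.float64)
    for i, c in enumerate(full_channels):
        if c in missing:
            data[i] = bad_data[missing.index(c)]
        else:
            data[i] = recording.data[recording.index_of(c)]
    return EEGRecording(
        data=data.astype(recording.data.dtype),
        rate=recording.rate,
        channels=tuple(full_channels),
        timestamps=recording.timestamps,
        participant=recording.participant,
    )


# ----------------------------------------------------------------------
# epoching


@dataclass
class EpochSet:
    """Per-participant epochs (trials x channels x samples) with labels."""

    epochs: np.ndarray
    labels: pd.DataFrame          # one row per epoch
    times_ms: np.ndarray          # sample times relative to the event
    rate: float
    channels: tuple[str, ...]
    window_ms: tuple[float, float] = (-500.0, 1500.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    drop_log: list = field(default_factory=list)

    def __post_init__(self):
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels must match epochs")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return EpochSet(
            epochs=self.epochs[idx],
            labels=self.labels.iloc[idx].reset_index(drop=True),
            times_ms=self.times_ms, rate=self.rate, channels=self.channels,
            window_ms=self.window_ms, baseline_ms=self.baseline_ms,
            drop_log=list(self.drop_log),
        )

    def channel(self, name: str) -> int:
        return self.channels.index(name)

    def average(self) -> np.ndarray:
        return self.epochs.mean(axis=0)


def epoch(
    recording: EEGRecording,
    events: pd.DataFrame,
    window_ms: tuple[float, float] = (-500.0, 1500.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    gaps: GapList | None = None,
) -> EpochSet:
    """Cut epochs around ``events`` (column ``time_s`` on the session clock).

    Windows are half-open ``(start, end]`` around the event sample;
    events whose epoch would cross a packet-loss gap or the recording
    boundary are dropped with a logged reason.  Per-channel baseline
    means over ``baseline_ms`` are subtracted when a baseline is given.
    """
    if gaps is None:
        gaps = detect_gaps(recording.timestamps, recording.rate)
    rate = recording.rate
    lo = ms_to_samples(window_ms[0], rate) + 1   # (start, end]
    hi = ms_to_samples(window_ms[1], rate)
    n_samp = hi - lo + 1
    times_ms = np.arange(lo, hi + 1) * 1000.0 / rate
    gap_after = {g.last_sample_before for g in gaps.gaps}

    ts = recording.timestamps
    period = 1.0 / rate
    in_span = events["time_s"].to_numpy()
    span_ok = (in_span >= ts[0] - 0.5 * period) & (in_span <= ts[-1] + 0.5 * period)
    aligned_iter = iter(
        align_markers(in_span[span_ok], ts, gaps) if span_ok.any() else []
    )
    keep_rows, cubes, drop_log = [], [], []
    for (row_idx, ev), ok in zip(events.iterrows(), span_ok):
        if not ok:
            drop_log.append((int(row_idx), "event outside recording"))
            continue
        mark = next(aligned_iter)
        a, b = mark.sample_index + lo, mark.sample_index + hi
        reason = None
        if mark.in_gap:
            reason = "event inside packet-loss gap"
        elif a < 0 or b >= recording.n_samples:
            reason = "epoch outside recording"
        elif any(a <= g < b for g in gap_after):
            reason = "epoch overlaps packet-loss gap"
        if reason:
            drop_log.append((int(row_idx), reason))
            continue
        keep_rows.append(row_idx)
        cubes.append(recording.data[:, a : b + 1].astype(np.float64))
    epochs = (
        np.stack(cubes) if cubes else np.empty((0, len(recording.channels), n_samp))
    )
    if baseline_ms is not None and len(epochs):
        bmask = (times_ms > baseline_ms[0]) & (times_ms <= baseline_ms[1])
        epochs = epochs - epochs[:, :, bmask].mean(axis=2, keepdims=True)
    labels = events.loc[keep_rows].reset_index(drop=True)
    return EpochSet(
        epochs=epochs, labels=labels, times_ms=times_ms, rate=rate,
        channels=recording.channels, window_ms=window_ms, baseline_ms=baseline_ms,
        drop_log=drop_log,
    )


# ----------------------------------------------------------------------
# rejection and balancing


def epoch_deviance(epochs: np.ndarray) -> np.ndarray:
    """Per-epoch statistic: peak absolute amplitude across channels."""
    return np.abs(epochs).max(axis=(1, 2))


def reject_3sd(epoch_set: EpochSet, n_sd: float = 3.0) -> EpochSet:
    """One-pass amplitude rejection: drop epochs whose peak absolute
    amplitude exceeds mean + ``n_sd`` SD across the pool."""
    if len(epoch_set) < 5:
        raise ValueError("need at least 5 epochs for the 3-SD rule")
    stat = epoch_deviance(epoch_set.epochs)
    sd = stat.std()
    if sd < 1e-12:
        return epoch_set.select(np.ones(len(epoch_set), dtype=bool))
    keep = stat <= stat.mean() + n_sd * sd
    out = epoch_set.select(keep)
    out.drop_log = list(epoch_set.drop_log) + [
        (int(i), "amplitude > 3 SD") for i in np.flatnonzero(~keep)
    ]
    return out


def match_counts(
    epochs_a: EpochSet, epochs_b: EpochSet, seed: int
) -> tuple[EpochSet, EpochSet]:
    """Equalize trial counts by seeded subsampling of the larger set
    (order preserved)."""
    na, nb = len(epochs_a), len(epochs_b)
    if na == 0 or nb == 0:
        raise ValueError("both epoch sets must be non-empty")
    n = min(na, nb)
    rng = np.random.default_rng(int(seed))

    def sub(es: EpochSet, size: int) -> EpochSet:
        if len(es) == size:
            return es
        idx = np.sort(rng.choice(len(es), size=size, replace=False))
        return es.select(idx)

    return sub(epochs_a, n), sub(epochs_b, n)
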