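"""Offline refinement of coarse voice-key markers into precise speech events.

The online voice-key reports onsets/offsets on a 100 ms grid.  For ERP
analysis each word is re-localized from the audio: the epoch around the
coarse marker is highpass filtered at 35 Hz, downsampled to 1470 Hz,
and three feature traces are computed — a smoothed amplitude envelope
(moving-average length 300), the first two mel-cepstral coefficient
traces, and a running RMS.  Abrupt mean changes in the RMS trace
(penalized exact segmentation) propose onset candidates; a candidate is
accepted only when the envelope rises and a cepstral trace changes
concurrently, which rejects lip smacks and other brief broadband
artifacts.  Offsets run the identical machinery on the time-reversed
epoch.  An accepted candidate is then localized to the threshold
crossing of a short-window envelope, giving millisecond-scale onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

REFINED = "refined"
COARSE_FALLBACK = "coarse_fallback"


@dataclass(frozen=True)
class OnsetConfig:
    epoch_window: tuple[float, float] = (-0.5, 1.0)  # seconds around the marker
    audio_rate: int = 44100
    highpass_cutoff: float = 35.0
    downsample_rate: int = 1470
    envelope_filter_length: int = 300     # samples on the 1470 Hz base
    envelope_lowpass: float = 730.0       # clamped to 0.95 x Nyquist
    n_cepstral_traces: int = 2
    cepstral_lowpass: float = 600.0       # clamped likewise
    cepstral_frame: int = 128
    cepstral_hop: int = 32
    n_mel_filters: int = 12
    changepoint_penalty: float = 3.0      # x var(trace) x log(n)
    min_segment: int = 16                 # samples between changepoints
    changepoint_decimation: int = 8       # decimate the smooth RMS before the DP
    validation_window_ms: float = 150.0   # matches the envelope smoothing scale
    min_rel_rise: float = 0.2             # of the epoch envelope peak
    cepstral_change_frac: float = 0.2     # of the trace's robust range
    min_peak_floor_ratio: float = 3.0     # envelope peak vs median (structure)
    localize_env_len: int = 15            # short-envelope MA (samples)
    localize_frac: float = 0.05           # threshold, fraction of plateau
    localize_span_ms: float = 250.0       # search span around the candidate
    localize_run_ms: float = 30.0         # sustained time above threshold

    def __post_init__(self):
        a, b = self.epoch_window
        if not (a < 0.0 < b):
            raise ValueError("epoch_window must span the coarse marker")
        ny = self.downsample_rate / 2.0
        if min(self.envelope_lowpass, self.cepstral_lowpass, ny) <= 0:
            raise ValueError("cutoffs and rates must be positive")
        if self.validation_window_ms <= 0:
            raise ValueError("validation_window must be positive")

    def clamped_cutoff(self, cutoff: float) -> float:
        return min(cutoff, 0.95 * self.downsample_rate / 2.0)


@dataclass
class FeatureSet:
    """Feature traces on the 1470 Hz epoch-relative time base."""

    downsampled: np.ndarray
    envelope: np.ndarray
    cepstra: np.ndarray       # (n_traces, n)
    rms: np.ndarray
    rate: int

    def __post_init__(self):
        n = self.downsampled.size
        if not (self.envelope.size == self.rms.size == n and self.cepstra.shape[1] == n):
            raise ValueError("feature traces must share one length")
        for arr in (self.downsampled, self.envelope, self.rms, self.cepstra):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite feature values")


@dataclass(frozen=True)
class SpeechEvent:
    participant: int
    trial: int
    word_position: int
    kind: str                  # "onset" | "offset"
    time: float                # seconds, session clock
    source: str                # REFINED | COARSE_FALLBACK


# ----------------------------------------------------------------------
# features


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # symmetric (linear-phase) kernel applied centered = zero phase
    return signal.fftconvolve(x, taps, mode="same")


@lru_cache(maxsize=32)
def _cached_firwin(numtaps: int, cutoff: float, fs: float, pass_zero) -> np.ndarray:
    return signal.firwin(numtaps, cutoff, fs=fs, pass_zero=pass_zero, window="hann")


def _moving_average(x: np.ndarray, length: int) -> np.ndarray:
    kernel = np.ones(length) / length
    return signal.fftconvolve(x, kernel, mode="same")


def _mel_filterbank(n_filters: int, n_fft: int, rate: float) -> np.ndarray:
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(rate / 2.0), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((n_fft // 2 + 1) * hz_pts / (rate / 2.0 + 1e-12)).astype(int)
    bins = np.clip(bins, 0, n_fft // 2)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        l, c, r = bins[i], bins[i + 1], bins[i + 2]
        if c > l:
            fb[i, l:c] = (np.arange(l, c) - l) / (c - l)
        if r > c:
            fb[i, c:r] = (r - np.arange(c, r)) / (r - c)
        fb[i, c if c < fb.shape[1] else -1] = 1.0
    return fb


def _mel_cepstral_traces(x: np.ndarray, config: OnsetConfig) -> np.ndarray:
    """First ``n_cepstral_traces`` mel-cepstral coefficients per frame,
    interpolated back onto the sample grid."""
    n, frame, hop = x.size, config.cepstral_frame, config.cepstral_hop
    if n < frame:
        raise ValueError("epoch shorter than one cepstral frame")
    starts = np.arange(0, n - frame + 1, hop)
    win = np.hanning(frame)
    frames = np.stack([x[s : s + frame] * win for s in starts])
    spec = np.abs(sp_fft.rfft(frames, axis=1)) ** 2
    fb = _mel_filterbank(config.n_mel_filters, frame, config.downsample_rate)
    logmel = np.log(spec @ fb.T + 1e-10)
    cep = sp_fft.dct(logmel, type=2, axis=1, norm="ortho")
    centers = starts + frame // 2
    grid = np.arange(n)
    traces = np.stack(
        [
            np.interp(grid, centers, cep[:, 1 + k])
            for k in range(config.n_cepstral_traces)
        ]
    )
    lp = config.clamped_cutoff(config.cepstral_lowpass)
    taps = _cached_firwin(31, lp, config.downsample_rate, True)
    return np.stack([_zero_phase_fir(tr, taps) for tr in traces])


def compute_features(audio_epoch: np.ndarray, config: OnsetConfig) -> FeatureSet:
    """Highpass -> downsample -> envelope + mel-cepstra + RMS traces."""
    a, b = config.epoch_window
    need = int(round((b - a) * config.audio_rate))
    if audio_epoch.size < need:
        raise ValueError(
            f"epoch has {audio_epoch.size} samples, window needs {need}"
        )
    x = np.asarray(audio_epoch, dtype=np.float64)
    # kernel long enough that the transition band stays below the cutoff
    hp = _cached_firwin(4001, config.highpass_cutoff, config.audio_rate, False)
    x = _zero_phase_fir(x, hp)
    q = config.audio_rate // config.downsample_rate
    if config.audio_rate != q * config.downsample_rate:
        raise ValueError("audio rate must be an integer multiple of the downsample rate")
    ds = signal.resample_poly(x, 1, q)

    env = _moving_average(np.abs(ds), config.envelope_filter_length)
    lp = config.clamped_cutoff(config.envelope_lowpass)
    taps = _cached_firwin(31, lp, config.downsample_rate, True)
    env = _zero_phase_fir(env, taps)

    rms = np.sqrt(
        np.maximum(_moving_average(ds**2, config.envelope_filter_length), 0.0)
    )
    cep = _mel_cepstral_traces(ds, config)
    return FeatureSet(
        downsampled=ds, envelope=env, cepstra=cep, rms=rms,
        rate=config.downsample_rate,
    )


# ----------------------------------------------------------------------
# changepoints


def _segment_cost_terms(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return s1, s2


def _cost(s1: np.ndarray, s2: np.ndarray, a, b):
    """L2 change-in-mean segment cost of [a, b) (vectorized in ``a``)."""
    n = b - a
    return (s2[b] - s2[a]) - (s1[b] - s1[a]) ** 2 / n


def detect_rms_changepoints(
    trace: np.ndarray, penalty: float | None = None, min_segment: int = 16,
    decimation: int = 1,
) -> list[int]:
    """Exact penalized segmentation of a 1-D trace (change in mean, L2 cost).

    Dynamic program over all admissible last-change positions (optimal
    partitioning); the penalty defaults to ``3 var(x) log n`` and scales
    with the trace.  ``decimation`` thins a smooth trace before the
    O(n^2) program and maps change indices back to the original grid.
    Returns sorted change indices (possibly empty).
    """
    x = np.asarray(trace, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty trace")
    dec = max(1, int(decimation))
    xd = x[::dec]
    min_seg = max(2, int(round(min_segment / dec)))
    n = xd.size
    if n < 2 * min_seg:
        return []
    var = float(np.var(xd))
    if var < 1e-24:
        return []
    pen = (3.0 * var * np.log(n)) if penalty is None else float(penalty)
    s1, s2 = _segment_cost_terms(xd)

    best = np.full(n + 1, np.inf)
    best[0] = -pen
    last = np.zeros(n + 1, dtype=int)
    all_starts = np.arange(n + 1)
    for t in range(min_seg, n + 1):
        starts = all_starts[: t - min_seg + 1]
        c = best[starts] + _cost(s1, s2, starts, t) + pen
        k = int(np.argmin(c))
        if np.isfinite(c[k]):
            best[t] = c[k]
            last[t] = starts[k]

    cps = []
    t = n
    while t > 0 and last[t] > 0:
        cps.append(last[t])
        t = last[t]
    return sorted(int(c * dec) for c in cps)


def best_single_split(trace: np.ndarray, min_segment: int = 2) -> int:
    """Exhaustive two-segment search: the split minimizing total L2 cost."""
    x = np.asarray(trace, dtype=np.float64)
    s1, s2 = _segment_cost_terms(x)
    n = x.size
    splits = np.arange(min_segment, n - min_segment + 1)
    costs = _cost(s1, s2, 0, splits) + _cost(s1, s2, splits, n)
    return int(splits[np.argmin(costs)])


# ----------------------------------------------------------------------
# validation + localization


def validate_candidates(
    candidates: list[int], features: FeatureSet, config: OnsetConfig
) -> int | None:
    """Earliest candidate with a concurrent envelope rise and cepstral change."""
    env, cep = features.envelope, features.cepstra
    n = env.size
    w = max(2, int(round(config.validation_window_ms * features.rate / 1000.0)))
    peak = float(env.max())
    if peak <= 0:
        return None
    # structureless epochs (silence / stationary noise) cannot carry speech
    if peak < config.min_peak_floor_ratio * float(np.median(env)):
        return None
    for c in sorted(candidates):
        lo, hi = max(0, c - w), min(n, c + w)
        if lo >= c or c >= hi:
            continue
        rise = float(env[c:hi].max() - np.median(env[lo:c]))
        if rise < config.min_rel_rise * peak:
            continue
        ok_cep = False
        for tr in cep:
            scale = float(np.percentile(tr, 95) - np.percentile(tr, 5)) + 1e-12
            change = abs(float(np.mean(tr[c:hi]) - np.mean(tr[lo:c])))
            if change >= config.cepstral_change_frac * scale:
                ok_cep = True
                break
        if ok_cep:
            return int(c)
    return None


def _localize(features: FeatureSet, candidate: int, config: OnsetConfig) -> float:
    """Sub-sample onset: short-envelope threshold crossing near the candidate."""
    ds = features.downsampled
    e = _moving_average(np.abs(ds), config.localize_env_len)
    span = int(round(config.localize_span_ms * features.rate / 1000.0))
    lo = max(0, candidate - span)
    hi = min(ds.size, candidate + span)
    plateau = float(e[candidate:hi].max()) if hi > candidate else float(e.max())
    thresh = config.localize_frac * plateau
    seg = e[lo:hi]
    above = (seg >= thresh).astype(int)
    # first sustained run above threshold (brief clicks cannot sustain it)
    run_len = max(3, int(round(config.localize_run_ms * features.rate / 1000.0)))
    if above.size < run_len:
        return float(candidate)
    runs = np.convolve(above, np.ones(run_len, dtype=int), mode="valid")
    hits = np.flatnonzero(runs == run_len)
    if hits.size == 0:
        return float(candidate)
    idx = int(hits[0])
    k = lo + idx
    if k > 0 and e[k] > e[k - 1]:
        # linear interpolation of the crossing
        frac = (thresh - e[k - 1]) / (e[k] - e[k - 1])
        frac = float(np.clip(frac, 0.0, 1.0))
        return k - 1 + frac
    return float(k)


# ----------------------------------------------------------------------
# top-level refinement


def _epoch_bounds(marker_s: float, config: OnsetConfig, n_audio: int) -> tuple[int, int]:
    a, b = config.epoch_window
    i0 = int(round((marker_s + a) * config.audio_rate))
    i1 = int(round((marker_s + b) * config.audio_rate))
    if marker_s < 0 or i1 > n_audio or i0 < 0:
        raise ValueError(
            f"marker at {marker_s:.3f}s: epoch [{i0}, {i1}) outside audio of "
            f"{n_audio} samples"
        )
    return i0, i1


def _refine_in_epoch(epoch: np.ndarray, config: OnsetConfig) -> float | None:
    """Epoch-relative refined index (on the 1470 Hz base) or None."""
    features = compute_features(epoch, config)
    var = float(np.var(features.rms[:: config.changepoint_decimation]))
    pen = config.changepoint_penalty * var * np.log(
        max(features.rms.size // max(1, config.changepoint_decimation), 2)
    )
    cands = detect_rms_changepoints(
        features.rms, penalty=pen, min_segment=config.min_segment,
        decimation=config.changepoint_decimation,
    )
    accepted = validate_candidates(cands, features, config)
    if accepted is None:
        return None
    return _localize(features, accepted, config)


def refine_onset(
    audio: np.ndarray,
    coarse_marker_s: float,
    config: OnsetConfig,
    participant: int = 0,
    trial: int = -1,
    word_position: int = -1,
) -> SpeechEvent:
    """Refine one coarse onset marker against the audio channel."""
    i0, i1 = _epoch_bounds(coarse_marker_s, config, audio.size)
    idx = _refine_in_epoch(np.asarray(audio[i0:i1], dtype=np.float64), config)
    if idx is None:
        return SpeechEvent(
            participant, trial, word_position, "onset",
            float(coarse_marker_s), COARSE_FALLBACK,
        )
    t = i0 / config.audio_rate + idx / config.downsample_rate
    return SpeechEvent(participant, trial, word_position, "onset", float(t), REFINED)


def refine_offset(
    audio: np.ndarray,
    coarse_marker_s: float,
    config: OnsetConfig,
    participant: int = 0,
    trial: int = -1,
    word_position: int = -1,
) -> SpeechEvent:
    """Refine one coarse offset marker (same procedure, time-reversed epoch)."""
    a, b = config.epoch_window
    # mirror the window so the word body lies where an onset's silence would
    mirrored = replace(config, epoch_window=(-b, -a))
    i0, i1 = _epoch_bounds(coarse_marker_s, mirrored, audio.size)
    epoch = np.asarray(audio[i0:i1], dtype=np.float64)[::-1]
    idx = _refine_in_epoch(epoch, config)
    if idx is None:
        return SpeechEvent(
            participant, trial, word_position, "offset",
            float(coarse_marker_s), COARSE_FALLBACK,
        )
    n_ds = int(epoch.size / (config.audio_rate // config.downsample_rate))
    t = i0 / config.audio_rate + (n_ds - 1 - idx) / config.downsample_rate
    return SpeechEvent(participant, trial, word_position, "offset", float(t), REFINED)


def refine_events(
    audio: np.ndarray,
    events: pd.DataFrame,
    config: OnsetConfig | None = None,
    participant: int | None = None,
    channel_of: dict | None = None,
) -> pd.DataFrame:
    """Refine all coarse voice-key markers of an event table.

    ``audio`` is (2, n) stereo (one channel per participant) or 1-D;
    rows with event_type ``speech_onset_coarse`` contribute an onset and
    an offset event (duration carries the coarse offset).
    """
    config = config or OnsetConfig()
    audio = np.atleast_2d(np.asarray(audio))
    rows = []
    spk = events[events.event_type == "speech_onset_coarse"]
    if participant is not None:
        spk = spk[spk.speaker == participant]
    for _, ev in spk.iterrows():
        p = int(ev.speaker)
        ch = (channel_of or {}).get(p, p - 1 if audio.shape[0] > 1 else 0)
        sig = audio[ch]
        on = refine_onset(sig, float(ev.onset_s), config, p, int(ev.trial),
                          int(ev.word_position))
        off = refine_offset(sig, float(ev.onset_s + ev.duration_s), config, p,
                            int(ev.trial), int(ev.word_position))
        if off.time <= on.time:  # degenerate refinement: keep coarse offset
            off = SpeechEvent(p, int(ev.trial), int(ev.word_position), "offset",
                              float(ev.onset_s + ev.duration_s), COARSE_FALLBACK)
        rows.extend([on.__dict__, off.__dict__])
    return pd.DataFrame(rows)


def score_events(detected: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Summary accuracy of refined events against planted ground truth.

    ``truth`` needs columns (participant, trial, word_position,
    true_onset_s, true_offset_s); returns bias/MAE in ms, the fraction
    within 20 ms, and the coarse-fallback rate.
    """
    t_on = truth.rename(columns={"true_onset_s": "true_time"})[
        ["participant", "trial", "word_position", "true_time"]
    ].assign(kind="onset")
    t_off = truth.rename(columns={"true_offset_s": "true_time"})[
        ["participant", "trial", "word_position", "true_time"]
    ].assign(kind="offset")
    merged = detected.merge(
        pd.concat([t_on, t_off]), on=["participant", "trial", "word_position", "kind"],
        how="inner",
    )
    refined = merged[merged.source == REFINED]
    err_ms = (refined.time - refined.true_time) * 1000.0
    return dict(
        n=len(merged),
        n_refined=len(refined),
        bias_ms=float(err_ms.mean()) if len(refined) else np.nan,
        mae_ms=float(err_ms.abs().mean()) if len(refined) else np.nan,
        median_abs_ms=float(err_ms.abs().median()) if len(refined) else np.nan,
        frac_within_20ms=float((err_ms.abs() <= 20.0).mean()) if len(refined) else np.nan,
        fallback_rate=float((merged.source == COARSE_FALLBACK).mean()),
    )
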