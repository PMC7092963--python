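"""Synthetic dyadic word-by-word sessions with known ground truth.

Emulates everything the downstream analysis consumes for one pair of
participants: the alternating word-event timeline (prime 2.5 s,
fixation 0.5 s, 1.5 s inter-trial blank, each word's visual display
triggered by the previous word's coarse voice-key offset), per-channel
stereo speech audio (harmonic voiced bursts, one channel per speaker),
two 24-channel 500 Hz EEG streams with planted ERP components
time-locked to the *partner's* true speech onsets, congruency-dependent
amplitude deltas on heard critical words, gamma-distributed reaction
times from an inverse-link linear predictor, speech-adjacent artifacts
(lip smacks, blinks, jaw EMG), 100 ms voice-key marker quantization and
optional Bluetooth-style packet loss.

Everything planted is recorded in a :class:`GroundTruth` table so tests
can score the pipeline against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .montage import CHANNELS, gaussian_topography
from .recording import EEGRecording
from .trial_design import CONGRUENT, INCONGRUENT, P1, P2, TrialPlan

# ----------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class ErpKernel:
    """One planted ERP component: a Gaussian-windowed half-sine bump."""

    peak_ms: float
    width_ms: float          # Gaussian SD of the window
    amplitude_uv: float      # signed peak amplitude at the center electrode
    center: str              # electrode where the topography peaks
    spread: float = 0.55     # topography width (unit-sphere chord)


def _default_kernels() -> dict:
    # peak latencies anchor to the grand-average peak topographies of
    # this paradigm (N100 114 ms, P200 250 ms, N400 480 ms) and the
    # midpoint of the 500-650 ms late-positivity analysis window
    return {
        "N100": ErpKernel(114.0, 25.0, -2.5, "Cz"),
        "P200": ErpKernel(250.0, 40.0, 5.0, "Fz"),
        "N400": ErpKernel(480.0, 50.0, -5.0, "CPz"),
        "P600": ErpKernel(600.0, 55.0, 4.0, "Pz"),
    }


@dataclass(frozen=True)
class RtModel:
    """Inverse-link gamma model for reading-aloud reaction times.

    The linear predictor eta (units 1/s) gives mean RT = 1/eta; RTs are
    gamma with the given shape.  Defaults put the grand-mean
    visual-to-speech latency near 0.49 s with a markedly slower first
    word, a small per-position trend, and congruency acting on the
    post-CW words (positions 8-13) of an incongruently primed speaker.
    """

    intercept: float = 2.10
    congruency_eta: float = 0.022     # incongruent -> larger eta -> faster
    word1_eta: float = -0.90
    position_slope_eta: float = 0.008  # per word position, centered on 7
    participant_sd: float = 0.10
    word_length_sd: float = 0.05
    gamma_shape: float = 25.0


@dataclass(frozen=True)
class ArtifactRates:
    blink_rate_per_min: float = 8.0
    blink_amp_uv: float = 200.0
    blink_width_ms: float = 80.0
    jaw_emg_uv: float = 20.0
    lip_smack_prob: float = 0.1
    lip_smack_amp: float = 0.12


@dataclass(frozen=True)
class Timing:
    prime_s: float = 2.5
    fixation_s: float = 0.5
    iti_s: float = 1.5
    word_duration_mean_s: float = 0.54
    word_duration_rel_sd: float = 0.11
    word_duration_letter_exp: float = 0.3
    mean_letters: float = 4.6
    attack_s: float = 0.030
    release_s: float = 0.050


@dataclass(frozen=True)
class SynthParams:
    audio_rate: int = 44100
    eeg_rate: float = 500.0
    channels: tuple[str, ...] = CHANNELS
    erp_kernels: dict = field(default_factory=_default_kernels)
    # additive amplitude deltas (uV) applied on incongruent heard CWs
    congruency_effects: dict = field(
        default_factory=lambda: {"P200": 2.0, "N400": -3.0, "P600": 2.0}
    )
    first_word_n100_gain: float = 2.0
    # single-trial latency jitter SD (ms); N400+P600 shift jointly as one
    # late cognitive cluster, the N100 is stimulus-locked
    latency_jitter_ms: dict = field(
        default_factory=lambda: {"N100": 0.0, "P200": 20.0, "late": 50.0}
    )
    rt_model: RtModel = field(default_factory=RtModel)
    artifacts: ArtifactRates = field(default_factory=ArtifactRates)
    timing: Timing = field(default_factory=Timing)
    marker_grid_s: float = 0.1
    # background EEG: amplitudes sized so that planted effects of a few
    # microvolts are recoverable at ~40 trials/condition
    n_noise_sources: int = 12
    noise_source_amp_uv: tuple[float, float] = (1.0, 2.2)
    noise_ar_coef: float = 0.985
    alpha_amp_uv: float = 2.0
    sensor_noise_uv: float = 0.6
    # packet loss: fraction of samples to drop (0 = none) or explicit spec
    packet_loss: object = None

    def validate(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("configuration error: zero EEG channels")
        for r in (self.audio_rate, self.eeg_rate, self.marker_grid_s):
            if r <= 0:
                raise ValueError("configuration error: rates must be positive")
        eff = self.congruency_effects
        if eff.get("P200", 0.0) < 0 or eff.get("P600", 0.0) < 0 or eff.get("N400", 0.0) > 0:
            raise ValueError(
                "congruency deltas must make incongruent more positive for "
                "P200/P600 and more negative for N400"
            )


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed like the event stream."""

    words: pd.DataFrame        # one row per spoken word
    erp_events: pd.DataFrame   # one row per heard-word event
    gaps: dict                 # participant -> list of (start_s, duration_s)

    def rts(self) -> pd.DataFrame:
        cols = [
            "participant", "trial", "word_position", "word", "word_length",
            "congruency", "rt_s", "t_visual_s", "true_onset_s", "true_offset_s",
        ]
        df = self.words.rename(columns={"speaker": "participant"})
        return df[cols].copy()


@dataclass
class SessionBundle:
    audio: np.ndarray | None     # (2, n) float32, channel p-1 per participant
    audio_rate: int
    eeg: dict                    # participant -> EEGRecording (may be empty)
    plan: TrialPlan
    events: pd.DataFrame         # coarse marker + visual event stream
    truth: GroundTruth
    params: SynthParams


# ----------------------------------------------------------------------
# word audio


def _envelope(n: int, rate: int, attack_s: float, release_s: float) -> np.ndarray:
    """Smooth amplitude envelope: raised-cosine attack/release, modulated sustain."""
    t = np.arange(n) / rate
    env = np.ones(n)
    na = max(2, int(attack_s * rate))
    nr = max(2, int(release_s * rate))
    env[:na] = 0.5 * (1 - np.cos(np.pi * np.arange(na) / na))
    env[-nr:] *= 0.5 * (1 + np.cos(np.pi * np.arange(nr) / nr))
    env *= 1.0 + 0.08 * np.sin(2 * np.pi * 3.0 * t)
    return env


def _word_duration(rng: np.random.Generator, n_letters: int, timing: Timing) -> float:
    det = timing.word_duration_mean_s * (
        n_letters / timing.mean_letters
    ) ** timing.word_duration_letter_exp
    z = rng.standard_normal()
    s = timing.word_duration_rel_sd
    return float(det * np.exp(s * z - 0.5 * s * s))


def synth_word_audio(
    n_letters: int, params: SynthParams, seed: int
) -> tuple[np.ndarray, float, float]:
    """Synthesize one spoken word: a harmonic voiced burst.

    Returns ``(waveform, true_onset_s, true_offset_s)`` with the onset
    and offset defined as the points where the amplitude envelope
    crosses 5% of its peak.  0.25 s of leading silence leaves room for
    an optional pre-onset lip-smack click; deterministic per seed.
    """
    if n_letters < 1:
        raise ValueError("n_letters must be >= 1")
    rng = np.random.default_rng(int(seed))
    return _word_audio(rng, n_letters, params)


def _word_audio(
    rng: np.random.Generator, n_letters: int, params: SynthParams,
    duration: float | None = None,
) -> tuple[np.ndarray, float, float]:
    rate = params.audio_rate
    timing = params.timing
    if duration is None:
        duration = _word_duration(rng, n_letters, timing)
    pre, post = 0.25, 0.10
    n_word = int(duration * rate)
    t = np.arange(n_word) / rate
    f0 = rng.uniform(110.0, 180.0)
    # slight vibrato keeps the harmonic stack naturalistic
    phase = 2 * np.pi * f0 * (t + 0.002 * np.sin(2 * np.pi * 5.0 * t))
    harmonics = np.array([1.0, 0.6, 0.8, 0.45, 0.3, 0.15])
    harmonics = harmonics * rng.uniform(0.7, 1.3, size=harmonics.size)
    x = np.zeros(n_word)
    for k, a in enumerate(harmonics, start=1):
        x += a * np.sin(k * phase)
    x /= np.abs(x).max() + 1e-12
    env = _envelope(n_word, rate, timing.attack_s, timing.release_s)
    x = 0.35 * env * x

    wav = np.zeros(int((pre + duration + post) * rate), dtype=np.float64)
    i0 = int(pre * rate)
    wav[i0 : i0 + n_word] = x

    thresh = 0.05 * env.max()
    above = np.flatnonzero(env >= thresh)
    onset = (i0 + above[0]) / rate
    offset = (i0 + above[-1]) / rate

    if rng.random() < params.artifacts.lip_smack_prob:
        lead = rng.uniform(0.05, 0.20)
        smack_t = onset - lead
        ns = int(0.010 * rate)
        j0 = int(smack_t * rate)
        if j0 >= 0:
            burst = rng.standard_normal(ns)
            burst = signal.sosfilt(
                signal.butter(4, 2000, "highpass", fs=rate, output="sos"), burst
            )
            burst *= params.artifacts.lip_smack_amp / (np.abs(burst).max() + 1e-12)
            wav[j0 : j0 + ns] += burst * np.hanning(ns)
    return wav, float(onset), float(offset)


# ----------------------------------------------------------------------
# timeline and reaction times


def _quantize_up(t: float, grid: float) -> float:
    """Voice-key quantization: detection reported on the next grid tick."""
    return float(np.ceil(t / grid - 1e-9) * grid)


def _rt_random_effects(rng: np.random.Generator, model: RtModel, word_lengths) -> tuple:
    u_p = {p: rng.normal(0.0, model.participant_sd) for p in (P1, P2)}
    u_wl = {
        int(wl): rng.normal(0.0, model.word_length_sd)
        for wl in sorted(set(int(w) for w in word_lengths))
    }
    return u_p, u_wl


def _rt_eta(model: RtModel, position: int, congruency: str, u_p: float, u_wl: float) -> float:
    eta = model.intercept + u_p + u_wl
    eta += model.position_slope_eta * (position - 7)
    if position == 1:
        eta += model.word1_eta
    if position >= 8 and congruency == INCONGRUENT:
        eta += model.congruency_eta
    return eta


def _draw_rt(rng, model: RtModel, eta: float) -> float:
    if eta <= 0:
        raise ValueError(
            f"inverse-link domain violation: linear predictor {eta:.3f} <= 0"
        )
    mu = 1.0 / eta
    return float(rng.gamma(model.gamma_shape, mu / model.gamma_shape))


def build_timeline(plan: TrialPlan, params: SynthParams, seed: int) -> pd.DataFrame:
    """Word-event timeline of a session (one row per spoken word).

    Columns carry the visual-presentation time, the drawn RT, true
    speech onset/offset, the 100 ms voice-key markers and congruency
    labels for both the speaker and the perceiving partner.
    """
    params.validate()
    rng = np.random.default_rng(int(seed))
    timing, model = params.timing, params.rt_model
    all_lengths = [
        len(w) for t in plan.trials for w in t.sentence.words
    ]
    u_p, u_wl = _rt_random_effects(rng, model, all_lengths)

    rows = []
    t_cursor = 0.0
    for trial in plan.trials:
        t_cursor += timing.fixation_s + timing.prime_s
        prev_coarse_offset = t_cursor
        for pos in range(1, 14):
            speaker = trial.speaker_of(pos)
            perceiver = P2 if speaker == P1 else P1
            word = trial.sentence.words[pos - 1]
            wl = len(word)
            t_visual = prev_coarse_offset
            eta = _rt_eta(model, pos, trial.congruency[speaker], u_p[speaker], u_wl[wl])
            rt = _draw_rt(rng, model, eta)
            onset = t_visual + rt
            duration = _word_duration(rng, wl, timing)
            offset = onset + duration
            coarse_on = _quantize_up(onset, params.marker_grid_s)
            coarse_off = _quantize_up(offset, params.marker_grid_s)
            rows.append(
                dict(
                    trial=trial.trial_index, word_position=pos, word=word,
                    word_length=wl, speaker=speaker, perceiver=perceiver,
                    congruency=trial.congruency[speaker],
                    congruency_perceiver=trial.congruency[perceiver],
                    is_cw=(pos == 8),
                    t_visual_s=t_visual, rt_s=rt,
                    true_onset_s=onset, true_offset_s=offset,
                    coarse_onset_s=coarse_on, coarse_offset_s=coarse_off,
                )
            )
            prev_coarse_offset = coarse_off
        t_cursor = prev_coarse_offset + timing.iti_s
    return pd.DataFrame(rows)


def synth_rts(plan: TrialPlan, params: SynthParams, seed: int) -> pd.DataFrame:
    """Stand-alone gamma RT table for one session (no audio/EEG).

    Same linear predictor and random-effect structure as the full
    session generator; deterministic per seed.
    """
    tl = build_timeline(plan, params, seed)
    tl = tl.rename(columns={"speaker": "participant"})
    return tl[
        [
            "participant", "trial", "word_position", "word", "word_length",
            "congruency", "rt_s",
        ]
    ].copy()


# ----------------------------------------------------------------------
# EEG synthesis


def _component_topo(kernel: ErpKernel, channels: tuple[str, ...]) -> np.ndarray:
    """Component topography in the analysis reference frame.

    Planted amplitudes are defined after linked-mastoid re-referencing:
    the Gaussian scalp weighting is shifted so the TP9/TP10 mean is
    zero and rescaled so the center electrode's weight stays exactly 1,
    making planted peak amplitudes invariant to the re-reference step.
    """
    topo = gaussian_topography(kernel.center, kernel.spread, channels=channels)
    if "TP9" in channels and "TP10" in channels:
        m = 0.5 * (topo[channels.index("TP9")] + topo[channels.index("TP10")])
        if m < 0.99:
            topo = (topo - m) / (1.0 - m)
    return topo


def _kernel_wave(kernel: ErpKernel, rate: float, amp: float) -> tuple[np.ndarray, int]:
    """Sampled bump and the sample offset of its first point w.r.t. event."""
    half = 3.0 * kernel.width_ms
    t = np.arange(-half, half + 1e-9, 1000.0 / rate)
    w = 2.0 * kernel.width_ms  # half-sine half-width
    hs = np.cos(np.pi * t / (2 * w))
    hs[np.abs(t) > w] = 0.0
    g = np.exp(-(t**2) / (2 * kernel.width_ms**2))
    wave = amp * hs * g
    first = int(round((kernel.peak_ms - half) * rate / 1000.0))
    return wave, first


def _add_at(data: np.ndarray, topo: np.ndarray, wave: np.ndarray, start: int) -> None:
    n = data.shape[1]
    a, b = max(start, 0), min(start + wave.size, n)
    if a >= b:
        return
    data[:, a:b] += topo[:, None] * wave[a - start : b - start][None, :]


def _background(
    rng: np.random.Generator, n_ch: int, n_samp: int, params: SynthParams
) -> np.ndarray:
    """Spatially correlated 1/f-type background + occipital alpha + sensor noise."""
    data = np.zeros((n_ch, n_samp), dtype=np.float64)
    pos_channels = params.channels
    for _ in range(params.n_noise_sources):
        src = signal.lfilter([1.0], [1.0, -params.noise_ar_coef], rng.standard_normal(n_samp))
        src /= src.std() + 1e-12
        amp = rng.uniform(*params.noise_source_amp_uv)
        center = pos_channels[rng.integers(len(pos_channels))]
        topo = gaussian_topography(center, spread=rng.uniform(0.4, 0.8), channels=pos_channels)
        data += amp * np.sign(rng.standard_normal()) * topo[:, None] * src[None, :]
    # 10 Hz alpha with slowly wandering amplitude, occipital emphasis
    t = np.arange(n_samp) / params.eeg_rate
    for center in ("O1", "O2"):
        f = rng.uniform(9.5, 10.5)
        slow = signal.lfilter([1.0], [1.0, -0.999], rng.standard_normal(n_samp))
        slow = 0.5 + 0.5 * (slow - slow.min()) / (np.ptp(slow) + 1e-12)
        topo = gaussian_topography(center, spread=0.5, channels=pos_channels)
        data += (
            params.alpha_amp_uv
            * slow
            * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            * topo[:, None]
        )
    data += params.sensor_noise_uv * rng.standard_normal((n_ch, n_samp))
    return data


def _emg_burst(rng, n: int, rate: float) -> np.ndarray:
    sos = signal.butter(4, (30.0, min(120.0, 0.45 * rate)), "bandpass", fs=rate, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / (x.std() + 1e-12)


def _synth_eeg_for(
    participant: int,
    timeline: pd.DataFrame,
    params: SynthParams,
    rng: np.random.Generator,
    n_samp: int,
) -> tuple[EEGRecording, list[dict]]:
    rate = params.eeg_rate
    chans = params.channels
    data = _background(rng, len(chans), n_samp, params)
    topos = {
        name: _component_topo(k, chans) for name, k in params.erp_kernels.items()
    }

    erp_rows = []
    heard = timeline[timeline["perceiver"] == participant]
    for _, ev in heard.iterrows():
        jit_p200 = rng.normal(0.0, params.latency_jitter_ms.get("P200", 0.0))
        jit_late = rng.normal(0.0, params.latency_jitter_ms.get("late", 0.0))
        jit_n100 = rng.normal(0.0, params.latency_jitter_ms.get("N100", 0.0))
        base = int(round(ev.true_onset_s * rate))
        row = dict(
            participant=participant, trial=int(ev.trial),
            word_position=int(ev.word_position),
            congruency=ev.congruency_perceiver, is_cw=bool(ev.is_cw),
            true_onset_s=ev.true_onset_s,
            jitter_p200_ms=jit_p200, jitter_late_ms=jit_late,
        )
        for name, k in params.erp_kernels.items():
            amp = k.amplitude_uv
            if name == "N100" and ev.word_position == 1:
                amp *= params.first_word_n100_gain
            if ev.is_cw and ev.congruency_perceiver == INCONGRUENT:
                amp += params.congruency_effects.get(name, 0.0)
            jit = jit_n100 if name == "N100" else (jit_p200 if name == "P200" else jit_late)
            wave, first = _kernel_wave(k, rate, amp)
            start = base + first + int(round(jit * rate / 1000.0))
            _add_at(data, topos[name], wave, start)
            row[f"amp_{name}_uv"] = amp
        erp_rows.append(row)

    # jaw EMG while this participant speaks
    emg_topo = sum(
        gaussian_topography(c, 0.35, channels=chans) for c in ("T7", "T8", "TP9", "TP10")
    )
    emg_topo = emg_topo / emg_topo.max()
    spoken = timeline[timeline["speaker"] == participant]
    if params.artifacts.jaw_emg_uv > 0:
        for _, ev in spoken.iterrows():
            a = int(ev.true_onset_s * rate)
            b = int(ev.true_offset_s * rate)
            if b > a and a < n_samp:
                b = min(b, n_samp)
                burst = _emg_burst(rng, b - a, rate) * params.artifacts.jaw_emg_uv
                data[:, a:b] += emg_topo[:, None] * burst[None, :] * np.hanning(b - a)

    # blinks: Poisson process over the session
    if params.artifacts.blink_rate_per_min > 0 and params.artifacts.blink_amp_uv > 0:
        n_blinks = rng.poisson(params.artifacts.blink_rate_per_min * n_samp / rate / 60.0)
        blink_topo = gaussian_topography("Fpz", 0.35, channels=chans)
        w_ms = params.artifacts.blink_width_ms
        tb = np.arange(-3 * w_ms, 3 * w_ms, 1000.0 / rate)
        blink_wave = params.artifacts.blink_amp_uv * np.exp(-(tb**2) / (2 * w_ms**2))
        for t0 in rng.uniform(0, n_samp / rate, size=n_blinks):
            _add_at(data, blink_topo, blink_wave, int(t0 * rate) - blink_wave.size // 2)

    rec = EEGRecording(
        data=data.astype(np.float32), rate=rate, channels=chans, participant=participant
    )
    return rec, erp_rows


def synth_rt_study(
    n_dyads: int,
    n_trials: int = 60,
    params: SynthParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """RT tables for several dyads with unique participant ids.

    Each dyad gets its own trial plan (fresh seeded shuffle of the
    built-in lexicon) and its own participant/word-length random
    intercept draws; rows carry the spoken-word sequence tag used by
    the reaction-time models.
    """
    from .lexicon import default_lexicon
    from .trial_design import DesignSpec, build_trial_plan

    params = params or SynthParams()
    rng = np.random.default_rng(int(seed))
    lexicon = default_lexicon(max(n_trials, 240), seed=0)
    spec = DesignSpec(n_trials=n_trials)
    frames = []
    for d in range(n_dyads):
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        plan = build_trial_plan(spec, lexicon, seed=int(s1))
        tab = synth_rts(plan, params, seed=int(s2))
        tab = tab.assign(
            dyad=d,
            participant=tab.participant + 2 * d,
        )
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out["sequence"] = out.word_position.map(
        lambda p: "cw_even" if p in (8, 10, 12) else
        ("cw_odd" if p in (9, 11, 13) else "other")
    )
    return out


def synth_heard_epochs(
    n_trials: int,
    params: SynthParams | None = None,
    seed: int = 0,
    incongruent: bool = False,
    noise_scale: float = 1.0,
    word_position: int = 8,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Directly synthesize heard-word epochs (no continuous session).

    Returns ``(cube, times_ms, truth)`` with cube trials x channels x
    samples on the analysis window (-500, 1500] ms at the EEG rate,
    planted component jitters/amplitudes recorded in ``truth``.  Used
    for focused component-recovery simulations.
    """
    params = params or SynthParams()
    rng = np.random.default_rng(int(seed))
    rate = params.eeg_rate
    n_t = 1000
    times_ms = (np.arange(n_t) - 249) * 1000.0 / rate
    event_idx = 249
    chans = params.channels
    topos = {
        name: _component_topo(k, chans) for name, k in params.erp_kernels.items()
    }
    if noise_scale > 0:
        bg = _background(rng, len(chans), n_trials * n_t, params) * noise_scale
        cube = np.transpose(bg.reshape(len(chans), n_trials, n_t), (1, 0, 2)).copy()
    else:
        cube = np.zeros((n_trials, len(chans), n_t))
    rows = []
    congr = INCONGRUENT if incongruent else CONGRUENT
    for i in range(n_trials):
        jit_p200 = rng.normal(0.0, params.latency_jitter_ms.get("P200", 0.0))
        jit_late = rng.normal(0.0, params.latency_jitter_ms.get("late", 0.0))
        row = dict(trial=i, word_position=word_position, congruency=congr,
                   jitter_p200_ms=jit_p200, jitter_late_ms=jit_late)
        for name, k in params.erp_kernels.items():
            amp = k.amplitude_uv
            if name == "N100" and word_position == 1:
                amp *= params.first_word_n100_gain
            if word_position == 8 and incongruent:
                amp += params.congruency_effects.get(name, 0.0)
            jit = 0.0 if name == "N100" else (jit_p200 if name == "P200" else jit_late)
            wave, first = _kernel_wave(k, rate, amp)
            _add_at(cube[i], topos[name], wave,
                    event_idx + first + int(round(jit * rate / 1000.0)))
            row[f"amp_{name}_uv"] = amp
        rows.append(row)
    # baseline-correct as the pipeline would
    bmask = (times_ms > -100.0) & (times_ms <= 0.0)
    cube -= cube[:, :, bmask].mean(axis=2, keepdims=True)
    return cube, times_ms, pd.DataFrame(rows)


# ----------------------------------------------------------------------
# packet loss


def inject_packet_loss(
    recording: EEGRecording, loss_spec, seed: int = 0
) -> tuple[EEGRecording, list[tuple[float, float]]]:
    """Drop sample runs to emulate Bluetooth packet loss.

    ``loss_spec`` is either a list of ``(start_s, duration_s)`` intervals
    or a float rate (fraction of samples to drop in random 20-200 ms
    gaps).  Timestamps keep real session time, so deltas across a gap
    exceed the nominal period; returns the shortened recording plus the
    realized gap intervals as ground truth.
    """
    rate = recording.rate
    n = recording.n_samples
    if loss_spec is None:
        return recording.copy_with(), []
    if np.isscalar(loss_spec):
        frac = float(loss_spec)
        if frac <= 0:
            return recording.copy_with(), []
        rng = np.random.default_rng(int(seed))
        intervals = []
        lost = 0
        guard = 0
        while lost < frac * n and guard < 10000:
            guard += 1
            dur = rng.uniform(0.02, 0.2)
            start = rng.uniform(1.0, n / rate - 1.0 - dur)
            if all(
                start + dur + 0.05 < s or start > s + d + 0.05 for s, d in intervals
            ):
                intervals.append((start, dur))
                lost += int(round(dur * rate))
        intervals.sort()
    else:
        intervals = sorted((float(s), float(d)) for s, d in loss_spec)
        for (s1, d1), (s2, _) in zip(intervals, intervals[1:]):
            if s1 + d1 > s2:
                raise ValueError("overlapping packet-loss intervals")
        for s, d in intervals:
            if s < 0 or s + d > n / rate:
                raise ValueError("loss interval outside recording span")

    keep = np.ones(n, dtype=bool)
    realized = []
    for s, d in intervals:
        a = int(np.ceil(s * rate))
        b = int(np.ceil((s + d) * rate))
        b = min(b, n)
        if b > a:
            keep[a:b] = False
            realized.append((a / rate, (b - a) / rate))
    out = EEGRecording(
        data=recording.data[:, keep],
        rate=rate,
        channels=recording.channels,
        timestamps=recording.timestamps[keep],
        participant=recording.participant,
    )
    return out, realized


# ----------------------------------------------------------------------
# full session


def _events_from_timeline(timeline: pd.DataFrame) -> pd.DataFrame:
    """The recorded marker stream: visual events + coarse voice-key markers."""
    rows = []
    for _, ev in timeline.iterrows():
        common = dict(
            trial=int(ev.trial), word_position=int(ev.word_position),
            speaker=int(ev.speaker),
            congruency=ev.congruency, congruency_perceiver=ev.congruency_perceiver,
        )
        rows.append(dict(onset_s=ev.t_visual_s, duration_s=0.0,
                         event_type="visual", **common))
        rows.append(dict(onset_s=ev.coarse_onset_s,
                         duration_s=ev.coarse_offset_s - ev.coarse_onset_s,
                         event_type="speech_onset_coarse", **common))
        rows.append(dict(onset_s=ev.coarse_offset_s, duration_s=0.0,
                         event_type="speech_offset_coarse", **common))
    return pd.DataFrame(rows).sort_values(
        ["onset_s", "trial", "word_position"], kind="stable"
    ).reset_index(drop=True)


def synth_session(
    plan: TrialPlan,
    params: SynthParams | None = None,
    seed: int = 0,
    include_audio: bool = True,
    include_eeg: bool = True,
) -> SessionBundle:
    """Generate one complete synthetic dyadic session.

    ``include_audio`` / ``include_eeg`` skip the respective heavy
    streams (the timeline, markers and ground truth are always built),
    which keeps targeted simulations cheap.
    """
    params = params or SynthParams()
    params.validate()
    rng = np.random.default_rng(int(seed))
    tl_seed, audio_seed, eeg1_seed, eeg2_seed, loss_seed = rng.integers(
        0, 2**31 - 1, size=5
    )
    timeline = build_timeline(plan, params, int(tl_seed))
    session_end = float(timeline.coarse_offset_s.max()) + params.timing.iti_s + 1.0

    audio = None
    if include_audio:
        arng = np.random.default_rng(int(audio_seed))
        n_audio = int(session_end * params.audio_rate)
        audio = np.zeros((2, n_audio), dtype=np.float32)
        onsets, offsets = [], []
        for i, ev in timeline.iterrows():
            wav, on_rel, off_rel = _word_audio(
                arng, int(ev.word_length), params, duration=ev.true_offset_s - ev.true_onset_s
            )
            start = int(round((ev.true_onset_s - on_rel) * params.audio_rate))
            a, b = max(start, 0), min(start + wav.size, n_audio)
            audio[ev.speaker - 1, a:b] += wav[a - start : b - start]
            onsets.append(start / params.audio_rate + on_rel)
            offsets.append(start / params.audio_rate + off_rel)
        # snap truth to the audio sample grid actually written
        timeline = timeline.assign(
            true_onset_s=onsets, true_offset_s=offsets
        )
        audio += (1e-4 * arng.standard_normal(audio.shape)).astype(np.float32)

    eeg = {}
    erp_rows: list[dict] = []
    gaps = {P1: [], P2: []}
    if include_eeg:
        n_samp = int(session_end * params.eeg_rate)
        for p, s in ((P1, eeg1_seed), (P2, eeg2_seed)):
            prng = np.random.default_rng(int(s))
            rec, rows = _synth_eeg_for(p, timeline, params, prng, n_samp)
            if params.packet_loss is not None:
                rec, realized = inject_packet_loss(
                    rec, params.packet_loss, seed=int(loss_seed) + p
                )
                gaps[p] = realized
            eeg[p] = rec
            erp_rows.extend(rows)

    truth = GroundTruth(
        words=timeline.copy(),
        erp_events=pd.DataFrame(erp_rows),
        gaps=gaps,
    )
    return SessionBundle(
        audio=audio, audio_rate=params.audio_rate, eeg=eeg, plan=plan,
        events=_events_from_timeline(timeline), truth=truth, params=params,
    )
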