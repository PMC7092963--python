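"""End-to-end orchestration: simulate -> refine -> repair -> preprocess ->
latency-corrected ERPs -> statistics, from one config and one master seed.

Each stage derives its own seed from the master seed, so any stage can
be re-run in isolation and the whole report is reproducible bit-for-bit
from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import erp_stats, rt_stats, speech_events, stream_repair
from ._utils import derive_seed
from .erp_core import (
    EpochSet, bandpass, calibrate_bursts, clean_bursts, detect_bad_channels,
    drop_channels, epoch, interpolate_channels, match_counts, reject_3sd,
    rereference,
)
from .lexicon import default_lexicon
from .montage import CHANNELS
from .recording import EEGRecording
from .ride import RideConfig, reconstruct_erp, ride_condition_erps, ride_decompose
from .synthetic_session import SessionBundle, SynthParams, synth_session
from .trial_design import CONGRUENT, INCONGRUENT, DesignSpec, build_trial_plan


@dataclass
class PipelineOptions:
    band: tuple[float, float] = (0.1, 30.0)
    use_burst_cleaning: bool = True
    burst_cutoff_k: float = 12.0
    detect_bads: bool = True
    reject_sd: float = 3.0
    baseline_ms: tuple[float, float] | None = (-100.0, 0.0)
    window_ms: tuple[float, float] = (-500.0, 1500.0)
    ride: RideConfig = field(default_factory=RideConfig)


@dataclass
class PipelineConfig:
    design: DesignSpec = field(default_factory=DesignSpec)
    synth: SynthParams = field(default_factory=SynthParams)
    onset: speech_events.OnsetConfig = field(default_factory=speech_events.OnsetConfig)
    options: PipelineOptions = field(default_factory=PipelineOptions)
    n_trials: int | None = 60     # overrides design.n_trials when set
    seed: int = 0


def select_calibration(recording: EEGRecording, window_s: float = 0.5,
                       max_s: float = 120.0) -> np.ndarray:
    """Calibration data for burst cleaning: windows sampled uniformly
    across the whole session (up to ``max_s`` seconds).

    Uniform sampling keeps typical task activity — including
    event-locked responses — inside the calibration statistics, so the
    robust per-direction thresholds flag only genuine bursts (blinks,
    motion) and never ordinary evoked activity.  The median/MAD
    statistics tolerate artifact windows as long as they are a
    minority.
    """
    n = int(window_s * recording.rate)
    starts = np.arange(0, recording.n_samples - n + 1, n)
    k = max(4, int(max_s / window_s))
    if len(starts) > k:
        starts = starts[np.linspace(0, len(starts) - 1, k).astype(int)]
    return np.concatenate([recording.data[:, s : s + n] for s in starts], axis=1)


def preprocess_stream(
    recording: EEGRecording,
    events: pd.DataFrame,
    options: PipelineOptions | None = None,
) -> tuple[EpochSet, dict]:
    """Filter, clean, re-reference, interpolate and epoch one stream.

    ``events`` needs a ``time_s`` column plus any label columns; the
    returned info dict logs bad channels, detected gaps and drops.
    """
    options = options or PipelineOptions()
    info: dict = {}
    rec = bandpass(recording, *options.band)
    bads: list[str] = []
    if options.detect_bads and rec.duration >= 60.0:
        bads = detect_bad_channels(rec)
    info["bad_channels"] = bads
    if bads:
        rec = drop_channels(rec, bads)
    if options.use_burst_cleaning:
        calib = calibrate_bursts(select_calibration(rec), rec.rate)
        rec = clean_bursts(rec, calib, cutoff_k=options.burst_cutoff_k)
    rec = rereference(rec)
    if bads:
        rec = interpolate_channels(rec, bads, full_channels=recording.channels)
    gaps = stream_repair.detect_gaps(rec.timestamps, rec.rate)
    info["n_gaps"] = len(gaps.gaps)
    es = epoch(rec, events, window_ms=options.window_ms,
               baseline_ms=options.baseline_ms, gaps=gaps)
    info["n_events"] = len(events)
    info["n_epochs"] = len(es)
    info["drop_log"] = es.drop_log
    return es, info


def heard_word_events(
    bundle: SessionBundle, participant: int, source: str = "truth",
    refined: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Event table (time_s + labels) of the words ``participant`` heard.

    ``source``: 'truth' uses the generator's exact onsets, 'refined'
    the offline speech-event refinement, 'coarse' the raw voice-key
    markers.
    """
    words = bundle.truth.words
    heard = words[words.perceiver == participant]
    if source == "truth":
        time_s = heard.true_onset_s
    elif source == "coarse":
        time_s = heard.coarse_onset_s
    elif source == "refined":
        if refined is None:
            raise ValueError("source='refined' needs the refined event table")
        on = refined[refined.kind == "onset"][
            ["participant", "trial", "word_position", "time"]
        ].rename(columns={"participant": "speaker_id"})
        merged = heard.merge(
            on, left_on=["speaker", "trial", "word_position"],
            right_on=["speaker_id", "trial", "word_position"], how="inner",
        )
        heard, time_s = merged, merged.time
    else:
        raise ValueError(f"unknown event source {source!r}")
    return pd.DataFrame({
        "time_s": time_s.to_numpy(),
        "trial": heard.trial.to_numpy(),
        "word_position": heard.word_position.to_numpy(),
        "congruency": heard.congruency_perceiver.to_numpy(),
        "is_cw": heard.is_cw.to_numpy(),
        "event_type": "heard",
    })


def cw_condition_erps(
    bundle: SessionBundle,
    participant: int,
    seed: int,
    options: PipelineOptions | None = None,
    source: str = "truth",
    refined: pd.DataFrame | None = None,
) -> dict:
    """Latency-corrected congruent/incongruent heard-CW ERPs for one
    participant: full preprocessing, count matching, decomposition."""
    options = options or PipelineOptions()
    events = heard_word_events(bundle, participant, source=source, refined=refined)
    es, info = preprocess_stream(bundle.eeg[participant], events, options)
    cw = es.select((es.labels.is_cw).to_numpy())
    out = {"info": info, "times_ms": es.times_ms, "channels": es.channels,
           "all_heard": es}
    conds = {}
    for label in (CONGRUENT, INCONGRUENT):
        sel = cw.select((cw.labels.congruency == label).to_numpy())
        if len(sel) >= 5:
            sel = reject_3sd(sel, options.reject_sd)
        conds[label] = sel
    a, b = match_counts(conds[CONGRUENT], conds[INCONGRUENT], seed)
    conds = {CONGRUENT: a, INCONGRUENT: b}
    out["n_per_condition"] = len(a)
    pooled = np.concatenate([a.epochs, b.epochs])
    labels = np.array([CONGRUENT] * len(a) + [INCONGRUENT] * len(b))
    erps, ride_res = ride_condition_erps(
        pooled, labels, es.times_ms, es.channels, options.ride
    )
    out["ride"] = ride_res
    for label, sel in conds.items():
        out[label] = {"epochs": sel, "erp": erps[label]}
    out["difference"] = out[INCONGRUENT]["erp"] - out[CONGRUENT]["erp"]
    return out


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Full demo pipeline on one synthetic session; returns the report
    bundle (plan counts, onset metrics, ERP effects, RT models)."""
    config = config or PipelineConfig()
    design = config.design
    if config.n_trials is not None and config.n_trials != design.n_trials:
        design = DesignSpec(
            n_trials=config.n_trials,
            frac_incongruent_per_participant=design.frac_incongruent_per_participant,
            frac_starter_p1=design.frac_starter_p1,
        )
    master = config.seed
    plan = build_trial_plan(
        design, default_lexicon(design.n_trials), seed=derive_seed(master, "plan")
    )
    bundle = synth_session(plan, config.synth, seed=derive_seed(master, "session"))
    report: dict = {"plan_counts": plan.counts, "seed": master}

    # speech-event refinement against ground truth
    refined = speech_events.refine_events(bundle.audio, bundle.events, config.onset)
    truth_words = bundle.truth.words.rename(columns={"speaker": "participant"})
    report["onset_metrics"] = speech_events.score_events(refined, truth_words)

    # ERP analysis per participant
    erp = {}
    for p in (1, 2):
        erp[p] = cw_condition_erps(
            bundle, p, seed=derive_seed(master, "preprocess") + p,
            options=config.options, source="refined", refined=refined,
        )
    report["erp"] = erp

    # window means + ANOVA across the two participants are not
    # meaningful (n=2); report per-participant window effects instead
    rows = []
    for p, res in erp.items():
        for comp, win in erp_stats.DEFAULT_WINDOWS.items():
            if comp == "N100":
                continue
            kern = config.synth.erp_kernels.get(comp)
            center = kern.center if kern else "CPz"
            polarity = 1 if comp in ("P200", "P600") else -1
            val = erp_stats.window_extremum(
                res["difference"], res["times_ms"], win.window_ms,
                res["channels"], center, polarity,
            )
            rows.append(dict(participant=p, component=comp,
                             difference_uv=val, site=center))
    report["erp_effects"] = pd.DataFrame(rows)

    # reaction times
    rt_table = rt_stats.extract_rts(refined, bundle.events, plan)
    rt_table, excl = rt_stats.filter_rts(rt_table)
    report["rt_table"] = rt_table
    report["rt_exclusions"] = excl
    return report
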