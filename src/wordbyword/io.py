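"""Serialization of plans, sessions, events and results.

Plain, diff-friendly formats wherever practical: trial plans and event
tables as tab-separated text with a JSON sidecar for the design spec,
audio as 16-bit PCM WAV, EEG as an .npz array bundle plus a JSON header
(channel labels, rate, participant) — a self-describing layout that
needs no EEG-specific binary dependencies.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .recording import EEGRecording
from .trial_design import (
    DesignSpec, SentenceTemplate, Trial, TrialPlan, PARTICIPANTS,
)

# ----------------------------------------------------------------------
# trial plans


def save_plan(plan: TrialPlan, path) -> None:
    """Plan as TSV (one row per trial) + '<path>.spec.json' for the spec."""
    path = Path(path)
    rows = []
    for t in plan.trials:
        row = dict(
            trial_index=t.trial_index,
            sentence_id=t.sentence.sentence_id,
            starter=t.starter,
            congruency_p1=t.congruency[1],
            congruency_p2=t.congruency[2],
            cw_speaker=t.cw_speaker,
            prime_p1=t.prime_for(1),
            prime_p2=t.prime_for(2),
            prime_a=t.sentence.prime_a,
            prime_b=t.sentence.prime_b,
        )
        for i, w in enumerate(t.sentence.words, start=1):
            row[f"word_{i:02d}"] = w
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    spec_path = path.with_suffix(path.suffix + ".spec.json")
    spec_path.write_text(json.dumps(dataclasses.asdict(plan.spec), indent=2))


def load_plan(path) -> TrialPlan:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    spec_path = path.with_suffix(path.suffix + ".spec.json")
    raw = json.loads(spec_path.read_text())
    if raw.get("incongruent_split") is not None:
        raw["incongruent_split"] = tuple(raw["incongruent_split"])
    spec = DesignSpec(**raw)
    word_cols = sorted(c for c in df.columns if c.startswith("word_"))
    trials = []
    for _, r in df.iterrows():
        sent = SentenceTemplate(
            sentence_id=r.sentence_id,
            words=tuple(str(r[c]) for c in word_cols),
            prime_a=str(r.prime_a),
            prime_b=str(r.prime_b),
        )
        congr = {1: str(r.congruency_p1), 2: str(r.congruency_p2)}
        trials.append(
            Trial(trial_index=int(r.trial_index), sentence=sent,
                  starter=int(r.starter), congruency=congr)
        )
    return TrialPlan(trials=tuple(trials), spec=spec)


# ----------------------------------------------------------------------
# events / tables


def save_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------------------------
# audio


def save_audio(audio: np.ndarray, rate: int, path) -> None:
    """Stereo float audio -> 16-bit PCM WAV (clipped at full scale)."""
    x = np.asarray(audio, dtype=np.float64)
    if x.ndim == 2:
        x = x.T  # scipy expects samples x channels
    pcm = np.clip(x, -1.0, 1.0)
    wavfile.write(path, int(rate), (pcm * 32767).astype(np.int16))


def load_audio(path) -> tuple[np.ndarray, int]:
    rate, data = wavfile.read(path)
    x = data.astype(np.float64) / 32767.0
    if x.ndim == 2:
        x = x.T
    return x, int(rate)


# ----------------------------------------------------------------------
# EEG


def save_recording(rec: EEGRecording, path) -> None:
    """EEG as '<path>.npz' (data + timestamps) + '<path>.json' header."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        data=rec.data.astype(np.float32),
        timestamps=rec.timestamps,
    )
    header = dict(
        rate=rec.rate, channels=list(rec.channels), participant=rec.participant,
        unit="uV", n_samples=int(rec.n_samples),
    )
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def load_recording(path) -> EEGRecording:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    return EEGRecording(
        data=arrays["data"],
        rate=float(header["rate"]),
        channels=tuple(header["channels"]),
        timestamps=arrays["timestamps"],
        participant=header.get("participant"),
    )


def save_session(bundle, out_dir) -> dict:
    """Write a synthetic session to a directory; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    save_plan(bundle.plan, out / "plan.tsv")
    paths["plan"] = out / "plan.tsv"
    save_events(bundle.events, out / "events.tsv")
    paths["events"] = out / "events.tsv"
    save_events(bundle.truth.words, out / "ground_truth_words.tsv")
    paths["truth"] = out / "ground_truth_words.tsv"
    if len(bundle.truth.erp_events):
        save_events(bundle.truth.erp_events, out / "ground_truth_erp.tsv")
    if bundle.audio is not None:
        save_audio(bundle.audio, bundle.audio_rate, out / "audio.wav")
        paths["audio"] = out / "audio.wav"
    for p, rec in bundle.eeg.items():
        save_recording(rec, out / f"eeg_p{p}")
        paths[f"eeg_p{p}"] = out / f"eeg_p{p}.npz"
    return paths
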