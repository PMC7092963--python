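"""Speech onset/offset refinement: features, changepoints, accuracy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wordbyword.lexicon import default_lexicon
from wordbyword.speech_events import (
    COARSE_FALLBACK, REFINED, OnsetConfig, best_single_split, compute_features,
    detect_rms_changepoints, refine_events, refine_offset, refine_onset,
    score_events, validate_candidates,
)
from wordbyword.speech_events import _refine_in_epoch
from wordbyword.synthetic_session import ArtifactRates, SynthParams, synth_session
from wordbyword.trial_design import DesignSpec, build_trial_plan

CFG = OnsetConfig()
EPOCH_N = int(1.5 * 44100)


def _session(smack=0.0, n_trials=12, seed=5):
    params = SynthParams(artifacts=ArtifactRates(
        lip_smack_prob=smack, blink_rate_per_min=0.0, jaw_emg_uv=0.0))
    plan = build_trial_plan(DesignSpec(n_trials=n_trials),
                            default_lexicon(max(n_trials, 240)), seed=1)
    return synth_session(plan, params, seed=seed, include_eeg=False)


@pytest.fixture(scope="module")
def clean_session():
    return _session(smack=0.0)


@pytest.fixture(scope="module")
def refined_clean(clean_session):
    return refine_events(clean_session.audio, clean_session.events, CFG)


class TestFeatures:
    def test_silence_gives_null_features(self):
        f = compute_features(np.zeros(EPOCH_N), CFG)
        assert np.abs(f.envelope).max() < 1e-9
        assert np.abs(f.rms).max() < 1e-9

    def test_dc_offset_erased_by_highpass(self):
        f = compute_features(np.full(EPOCH_N, 0.5), CFG)
        mid = slice(400, 1800)  # away from convolution edges
        assert np.abs(f.envelope[mid]).max() < 5e-3
        assert np.abs(f.rms[mid]).max() < 5e-3

    def test_step_response_of_smoother(self):
        """A tone switched on mid-epoch drives the envelope from ~0 to a
        steady level across the moving-average length."""
        t = np.arange(EPOCH_N) / 44100.0
        x = np.sin(2 * np.pi * 220 * t) * (t >= 0.75)
        f = compute_features(x, CFG)
        i_on = int(0.75 * 1470)
        L = CFG.envelope_filter_length
        pre = np.abs(f.envelope[: i_on - L]).max()
        post = np.median(f.envelope[i_on + L : i_on + 3 * L])
        assert pre < 0.05 * post
        # ramp spans roughly the filter length (centered smoother)
        rise = f.envelope[i_on - L : i_on + L]
        assert rise[0] < 0.2 * post and rise[-1] > 0.8 * post

    def test_traces_share_length_and_rate(self):
        f = compute_features(np.random.default_rng(0).standard_normal(EPOCH_N), CFG)
        assert f.envelope.size == f.rms.size == f.downsampled.size
        assert f.cepstra.shape == (CFG.n_cepstral_traces, f.rms.size)


class TestChangepoints:
    def test_constant_trace_no_candidates(self):
        assert detect_rms_changepoints(np.ones(200)) == []

    def test_single_step_matches_exhaustive_search(self):
        x = np.zeros(100)
        x[40:] = 1.0
        got = detect_rms_changepoints(x, min_segment=2)
        assert got == [best_single_split(x)] == [40]

    def test_two_steps_recovered(self):
        x = np.zeros(150)
        x[50:100] = 2.0
        assert detect_rms_changepoints(x, min_segment=2) == [50, 100]

    @given(st.integers(10, 90), st.floats(0.5, 5.0),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_noisy_single_step_equals_two_segment_oracle(self, m, height, seed):
        """When the optimal partition has one change, it coincides with
        the exhaustive two-segment argmin."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 0.1, 100)
        x[m:] += height
        got = detect_rms_changepoints(x, min_segment=2)
        if len(got) == 1:
            assert got == [best_single_split(x)]
            assert abs(got[0] - m) <= 2

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            detect_rms_changepoints(np.array([]))


class TestValidation:
    def test_empty_candidates_none(self):
        f = compute_features(np.random.default_rng(1).standard_normal(EPOCH_N) * 1e-4,
                             CFG)
        assert validate_candidates([], f, CFG) is None

    def test_silence_only_epoch_falls_back(self):
        ev = refine_onset(np.random.default_rng(2).normal(0, 1e-4, 5 * 44100),
                          1.0, CFG)
        assert ev.source == COARSE_FALLBACK
        assert ev.time == 1.0


class TestRefinement:
    def test_onset_accuracy_clean(self, clean_session, refined_clean):
        truth = clean_session.truth.words.rename(columns={"speaker": "participant"})
        m = score_events(refined_clean, truth)
        assert m["fallback_rate"] <= 0.05
        assert m["median_abs_ms"] <= 5.0
        assert abs(m["bias_ms"]) <= 2.0
        assert m["frac_within_20ms"] >= 0.95

    def test_offsets_follow_onsets(self, refined_clean):
        piv = refined_clean.pivot_table(
            index=["participant", "trial", "word_position"],
            columns="kind", values="time")
        assert (piv["offset"] > piv["onset"]).all()

    def test_refined_finer_than_voice_key_grid(self, refined_clean):
        refined = refined_clean[refined_clean.source == REFINED]
        on_grid = np.isclose(refined.time % 0.1, 0, atol=1e-9) | \
            np.isclose(refined.time % 0.1, 0.1, atol=1e-9)
        assert on_grid.mean() < 0.05

    def test_onsets_increase_within_trial(self, refined_clean):
        on = refined_clean[refined_clean.kind == "onset"]
        for _, g in on.groupby("trial"):
            assert (np.diff(g.sort_values("word_position").time) > 0).all()

    def test_deterministic(self, clean_session):
        ev = clean_session.events[
            clean_session.events.event_type == "speech_onset_coarse"].iloc[3]
        a = refine_onset(clean_session.audio[ev.speaker - 1], ev.onset_s, CFG)
        b = refine_onset(clean_session.audio[ev.speaker - 1], ev.onset_s, CFG)
        assert a == b

    def test_double_reversal_is_identity(self, clean_session):
        ev = clean_session.events[
            clean_session.events.event_type == "speech_onset_coarse"].iloc[4]
        i0 = int((ev.onset_s - 0.5) * 44100)
        epoch = clean_session.audio[ev.speaker - 1][i0:i0 + EPOCH_N].astype(float)
        assert _refine_in_epoch(epoch, CFG) == _refine_in_epoch(epoch[::-1][::-1], CFG)

    def test_marker_outside_audio_raises(self):
        with pytest.raises(ValueError, match="outside"):
            refine_onset(np.zeros(44100), 5.0, CFG)
        with pytest.raises(ValueError, match="outside"):
            refine_offset(np.zeros(44100), 5.0, CFG)


class TestLipSmackRobustness:
    def test_false_early_onset_rate(self):
        """With lip smacks planted before 30% of words, early-by-more-
        than-30-ms onsets stay rare and accuracy is preserved."""
        b = _session(smack=0.3, seed=9)
        det = refine_events(b.audio, b.events, CFG)
        truth = b.truth.words.rename(columns={"speaker": "participant"})
        on = det[(det.kind == "onset") & (det.source == REFINED)].merge(
            truth[["participant", "trial", "word_position", "true_onset_s"]],
            on=["participant", "trial", "word_position"])
        err_ms = (on.time - on.true_onset_s) * 1000
        assert (err_ms < -30).mean() <= 0.05
        assert err_ms.abs().median() <= 5.0


class TestScoring:
    def _truth(self):
        return pd.DataFrame({
            "participant": [1, 1], "trial": [0, 0], "word_position": [1, 2],
            "true_onset_s": [1.0, 2.0], "true_offset_s": [1.5, 2.5],
        })

    def test_exact_detection_scores_zero_error(self):
        det = pd.DataFrame({
            "participant": [1, 1], "trial": [0, 0], "word_position": [1, 2],
            "kind": ["onset", "onset"], "time": [1.0, 2.0],
            "source": [REFINED, REFINED],
        })
        m = score_events(det, self._truth())
        assert m["bias_ms"] == 0 and m["mae_ms"] == 0
        assert m["frac_within_20ms"] == 1.0 and m["fallback_rate"] == 0.0

    def test_constant_offset_detection(self):
        det = pd.DataFrame({
            "participant": [1, 1], "trial": [0, 0], "word_position": [1, 2],
            "kind": ["onset", "onset"], "time": [1.010, 2.010],
            "source": [REFINED, REFINED],
        })
        m = score_events(det, self._truth())
        assert m["bias_ms"] == pytest.approx(10.0)
        assert m["mae_ms"] == pytest.approx(10.0)

    def test_metrics_match_brute_force(self, rng):
        n = 40
        truth = pd.DataFrame({
            "participant": np.repeat([1, 2], n // 2),
            "trial": np.tile(np.arange(n // 2), 2),
            "word_position": 1,
            "true_onset_s": np.linspace(1, 100, n),
            "true_offset_s": np.linspace(1.5, 100.5, n),
        })
        errs = rng.normal(0, 0.01, n)
        det = pd.DataFrame({
            "participant": truth.participant, "trial": truth.trial,
            "word_position": 1, "kind": "onset",
            "time": truth.true_onset_s + errs, "source": REFINED,
        })
        m = score_events(det, truth)
        assert m["bias_ms"] == pytest.approx(errs.mean() * 1000)
        assert m["mae_ms"] == pytest.approx(np.abs(errs).mean() * 1000)
        assert m["frac_within_20ms"] == pytest.approx((np.abs(errs) <= 0.02).mean())
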