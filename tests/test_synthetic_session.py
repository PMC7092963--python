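"""Synthetic session generator: timing, markers, RTs, planted effects."""

import numpy as np
import pandas as pd
import pytest

from wordbyword.recording import EEGRecording
from wordbyword.synthetic_session import (
    ArtifactRates, RtModel, SynthParams, build_timeline, inject_packet_loss,
    synth_heard_epochs, synth_rt_study, synth_rts, synth_session,
    synth_word_audio,
)
from wordbyword.montage import CHANNELS
from wordbyword.trial_design import INCONGRUENT


class TestWordAudio:
    def test_silence_before_onset(self, clean_params):
        # onset = 5% envelope crossing, so the pre-onset signal stays
        # below that fraction of the peak and is exactly zero earlier
        wav, onset, offset = synth_word_audio(5, clean_params, seed=1)
        i_on = int(onset * clean_params.audio_rate)
        peak = np.abs(wav).max()
        assert np.abs(wav[:i_on]).max() <= 0.06 * peak
        assert np.abs(wav[: i_on - int(0.02 * clean_params.audio_rate)]).max() == 0
        assert offset > onset

    def test_deterministic(self, clean_params):
        a = synth_word_audio(5, clean_params, seed=42)
        b = synth_word_audio(5, clean_params, seed=42)
        assert np.array_equal(a[0], b[0]) and a[1:] == b[1:]

    def test_duration_model_calibration(self, clean_params):
        """Monte-Carlo mean duration at lexicon-typical word lengths
        matches the configured 0.54 s within the configured spread."""
        lengths = [4, 5, 3, 6, 3, 6, 4, 5, 3, 5, 7, 3, 6]
        durs = [
            (lambda w: w[2] - w[1])(synth_word_audio(lengths[s % 13],
                                                     clean_params, seed=s))
            for s in range(500)
        ]
        assert abs(np.mean(durs) - 0.54) < 0.05

    def test_duration_monotone_in_letters_at_fixed_seed(self, clean_params):
        durs = [
            (lambda w: w[2] - w[1])(synth_word_audio(n, clean_params, seed=9))
            for n in (2, 4, 6, 8)
        ]
        assert all(np.diff(durs) > 0)


class TestTimeline:
    def test_event_counts_and_monotonic_onsets(self, small_plan, clean_params):
        tl = build_timeline(small_plan, clean_params, seed=0)
        assert len(tl) == 13 * len(small_plan)
        for _, g in tl.groupby("trial"):
            assert (np.diff(g.sort_values("word_position").true_onset_s) > 0).all()
            # speakers alternate word by word
            assert (g.sort_values("word_position").speaker.diff().dropna() != 0).all()

    def test_voice_key_quantization(self, small_plan, clean_params):
        tl = build_timeline(small_plan, clean_params, seed=0)
        grid = clean_params.marker_grid_s
        assert np.allclose(np.round(tl.coarse_onset_s / grid) * grid,
                           tl.coarse_onset_s, atol=1e-9)
        diffs = tl.coarse_onset_s - tl.true_onset_s
        assert (diffs >= 0).all() and (diffs < grid).all()

    def test_visual_triggered_by_previous_coarse_offset(self, small_plan,
                                                        clean_params):
        tl = build_timeline(small_plan, clean_params, seed=0)
        for _, g in tl.groupby("trial"):
            g = g.sort_values("word_position")
            assert np.allclose(g.t_visual_s.to_numpy()[1:],
                               g.coarse_offset_s.to_numpy()[:-1])


class TestSession:
    def test_marker_stream_matches_plan(self, small_plan, clean_params):
        b = synth_session(small_plan, clean_params, seed=5,
                          include_audio=False, include_eeg=False)
        onsets = b.events[b.events.event_type == "speech_onset_coarse"]
        assert len(onsets) == 13 * len(small_plan)
        # marker speaker labels follow the plan's alternation
        for t in small_plan.trials:
            g = onsets[onsets.trial == t.trial_index]
            for _, row in g.iterrows():
                assert row.speaker == t.speaker_of(row.word_position)

    def test_eeg_audio_clock_consistency(self, small_plan, clean_params):
        b = synth_session(small_plan, clean_params, seed=5)
        rate = clean_params.eeg_rate
        idx = (b.truth.words.true_onset_s * rate).round()
        back = idx / rate
        assert (np.abs(back - b.truth.words.true_onset_s)
                <= 0.5 / rate + 1e-9).all()
        assert b.audio.shape[1] / b.audio_rate == pytest.approx(
            b.eeg[1].n_samples / rate, abs=1.0)

    def test_one_erp_event_per_heard_word(self, small_plan, clean_params):
        b = synth_session(small_plan, clean_params, seed=5, include_audio=False)
        # every spoken word is heard by exactly one participant
        assert len(b.truth.erp_events) == 13 * len(small_plan)
        key = ["participant", "trial", "word_position"]
        assert not b.truth.erp_events.duplicated(subset=key).any()

    def test_invalid_params_rejected(self, small_plan):
        with pytest.raises(ValueError, match="channels"):
            synth_session(small_plan, SynthParams(channels=()), seed=0)
        with pytest.raises(ValueError, match="incongruent"):
            SynthParams(congruency_effects={"N400": +3.0}).validate()


class TestPlantedEffects:
    def test_null_deltas_give_null_difference(self):
        """With zero congruency deltas the condition difference wave is
        sampling noise only (RMS far below the default planted deltas)."""
        p = SynthParams(congruency_effects={"P200": 0.0, "N400": 0.0, "P600": 0.0})
        cc, times, _ = synth_heard_epochs(150, p, seed=1, incongruent=False)
        ci, _, _ = synth_heard_epochs(150, p, seed=2, incongruent=True)
        d = ci.mean(axis=0) - cc.mean(axis=0)
        m = (times >= 300) & (times <= 650)
        assert np.sqrt(np.mean(d[CHANNELS.index("CPz"), m] ** 2)) < 0.7

    def test_n400_delta_recovered_in_average(self):
        """Difference wave of averaged heard-CW epochs shows the planted
        -3 uV N400 delta (smeared by latency jitter) at CPz."""
        p = SynthParams()
        cc, times, _ = synth_heard_epochs(200, p, seed=3, incongruent=False)
        ci, _, _ = synth_heard_epochs(200, p, seed=4, incongruent=True)
        d = ci.mean(axis=0) - cc.mean(axis=0)
        m = (times >= 350) & (times <= 550)
        trough = d[CHANNELS.index("CPz"), m].min()
        smear = 50.0 / np.hypot(50.0, 50.0)  # width vs jitter SD
        assert trough == pytest.approx(-3.0 * smear, abs=0.8)
        assert trough < -1.0


class TestPacketLoss:
    def _rec(self, n=30000):
        rng = np.random.default_rng(0)
        return EEGRecording(data=rng.standard_normal((24, n)).astype(np.float32))

    def test_gap_arithmetic(self):
        out, realized = inject_packet_loss(self._rec(), [(10.0, 0.1)])
        assert self._rec().n_samples - out.n_samples == 50
        assert realized == [(10.0, 0.1)]

    def test_empty_loss_identity(self):
        rec = self._rec()
        out, realized = inject_packet_loss(rec, [])
        assert realized == []
        assert np.array_equal(out.data, rec.data)
        assert np.array_equal(out.timestamps, rec.timestamps)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            inject_packet_loss(self._rec(), [(10.0, 0.2), (10.1, 0.2)])

    def test_roundtrip_with_gap_detection(self):
        from wordbyword.stream_repair import detect_gaps

        rec = self._rec()
        out, realized = inject_packet_loss(rec, 0.01, seed=3)
        det = detect_gaps(out.timestamps, rec.rate)
        got = [(g.start_s, g.n_lost) for g in det.gaps]
        exp = [(s, int(round(d * rec.rate))) for s, d in realized]
        assert [(pytest.approx(s, abs=1e-6), n) for s, n in got] == exp


class TestReactionTimes:
    def test_deterministic(self, small_plan, clean_params):
        a = synth_rts(small_plan, clean_params, seed=11)
        b = synth_rts(small_plan, clean_params, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_gamma_mean_matches_inverse_link(self, small_plan):
        """With all effects zero and intercept 1/0.7, the sample mean
        over many draws approaches 0.7 s (law of large numbers)."""
        p = SynthParams(rt_model=RtModel(
            intercept=1.0 / 0.7, congruency_eta=0.0, word1_eta=0.0,
            position_slope_eta=0.0, participant_sd=0.0, word_length_sd=0.0,
        ))
        tabs = [synth_rts(small_plan, p, seed=s) for s in range(70)]
        rts = pd.concat(tabs).rt_s
        assert len(rts) >= 10_000
        assert rts.mean() == pytest.approx(0.7, abs=0.01)

    def test_nonpositive_predictor_raises(self, small_plan):
        p = SynthParams(rt_model=RtModel(intercept=0.5, word1_eta=-0.9,
                                         participant_sd=0.0))
        with pytest.raises(ValueError, match="inverse-link"):
            synth_rts(small_plan, p, seed=0)

    def test_study_unique_participants(self):
        tab = synth_rt_study(3, n_trials=12, seed=0)
        assert tab.participant.nunique() == 6
        assert set(tab.sequence) <= {"cw_even", "cw_odd", "other"}
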