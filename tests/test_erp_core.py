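"""EEG preprocessing: filtering, bad channels, burst cleaning,
re-referencing, spherical-spline interpolation, epoching, rejection."""

import numpy as np
import pandas as pd
import pytest

from wordbyword.erp_core import (
    EpochSet, bandpass, calibrate_bursts, clean_bursts, detect_bad_channels,
    drop_channels, epoch, epoch_deviance, interpolate_channels, match_counts,
    reject_3sd, rereference, interpolation_matrix,
)
from wordbyword.montage import CHANNELS, gaussian_topography, position_matrix
from wordbyword.recording import EEGRecording


def _structured_background(rng, n, amp=4.0):
    """Spatially correlated noise (real EEG channels co-vary)."""
    from scipy import signal as sg
    centers = ("Cz", "P3", "F8", "O1", "FC1", "T7")
    topos = np.stack([gaussian_topography(c, 0.6) for c in centers])
    srcs = sg.lfilter([1.0], [1.0, -0.98], rng.standard_normal((len(centers), n)), axis=1)
    srcs /= srcs.std(axis=1, keepdims=True)
    return amp * (topos.T @ srcs) + 1.0 * rng.standard_normal((24, n))


class TestBandpass:
    def _tone(self, f, dur=120.0):
        t = np.arange(0, dur, 1 / 500.0)
        return EEGRecording(data=np.tile(np.sin(2 * np.pi * f * t), (24, 1)))

    def test_passband_preserved(self):
        out = bandpass(self._tone(10.0))
        mid = slice(10000, 50000)
        ratio = out.data[0, mid].std() / self._tone(10.0).data[0, mid].std()
        assert abs(ratio - 1.0) < 0.05
        # zero phase: peak positions unchanged
        ref = self._tone(10.0).data[0, mid]
        lag = np.argmax(np.correlate(out.data[0, mid][:2000], ref[:2000], "full")) \
            - 1999
        assert abs(lag) <= 1

    def test_stopband_attenuated(self):
        out = bandpass(self._tone(50.0))
        mid = slice(10000, 50000)
        ratio = out.data[0, mid].std() / self._tone(50.0).data[0, mid].std()
        assert 20 * np.log10(ratio + 1e-12) < -20.0

    def test_dc_removed(self):
        rec = EEGRecording(data=np.full((24, 60000), 7.0))
        out = bandpass(rec)
        assert np.abs(out.data[0, 20000:40000]).max() < 0.07

    def test_invalid_band_raises(self):
        with pytest.raises(ValueError, match="invalid band"):
            bandpass(self._tone(10.0), low=30.0, high=0.1)


class TestBadChannels:
    def _rec(self, rng):
        return EEGRecording(data=_structured_background(rng, 40000))

    def test_clean_recording_empty(self, rng):
        assert detect_bad_channels(self._rec(rng)) == []

    def test_flat_channel_flagged(self, rng):
        rec = self._rec(rng)
        i = rec.index_of("C3")
        rec.data[i] = 0.0
        assert detect_bad_channels(rec) == ["C3"]

    def test_noise_channel_flagged_by_correlation(self, rng):
        rec = self._rec(rng)
        i = rec.index_of("P4")
        rec.data[i] = 50.0 * rng.standard_normal(rec.n_samples)
        assert "P4" in detect_bad_channels(rec)

    def test_short_recording_rejected(self, rng):
        rec = EEGRecording(data=rng.standard_normal((24, 1000)))
        with pytest.raises(ValueError, match="60"):
            detect_bad_channels(rec)


class TestBurstCleaning:
    def test_calibration_like_data_unchanged(self, rng):
        calib = _structured_background(rng, 30000)
        rec = EEGRecording(data=calib[:, :20000].copy())
        out = clean_bursts(rec, calib, cutoff_k=10.0)
        assert np.abs(out.data - rec.data).max() < 1e-9

    def test_huge_cutoff_is_identity(self, rng):
        data = _structured_background(rng, 20000)
        data[:, 5000:5300] += 300.0  # a burst that k=inf must ignore
        rec = EEGRecording(data=data)
        out = clean_bursts(rec, _structured_background(rng, 30000), cutoff_k=1e9)
        assert np.array_equal(out.data, rec.data)

    def test_blink_suppressed_erp_preserved(self, rng):
        """Planted 400 uV frontal blinks lose >= 80% variance while a
        5 uV centro-parietal component changes <= 10%."""
        calib = _structured_background(rng, 30000)
        data = _structured_background(rng, 60000)
        erp_topo = gaussian_topography("CPz", 0.55)
        erp = 5 * np.exp(-((np.arange(200) - 100) ** 2) / (2 * 25.0**2))
        starts = list(range(1000, 59000, 1000))
        for s in starts:
            data[:, s:s + 200] += erp_topo[:, None] * erp[None, :]
        ref = data.copy()
        blink_topo = gaussian_topography("Fpz", 0.35)
        blink = 400 * np.exp(-((np.arange(300) - 150) ** 2) / (2 * 40.0**2))
        # blinks placed clear of the planted component segments
        bstarts = list(range(2450, 59000, 2000))
        for s in bstarts:
            data[:, s:s + 300] += blink_topo[:, None] * blink[None, :]
        out = clean_bursts(EEGRecording(data=data), calib)
        fp1, cpz = CHANNELS.index("Fp1"), CHANNELS.index("CPz")
        mask = np.zeros(60000, bool)
        for s in bstarts:
            mask[s:s + 300] = True
        assert out.data[fp1, mask].var() < 0.2 * data[fp1, mask].var()
        avg = lambda d: np.mean([d[cpz, s:s + 200] for s in starts], axis=0)
        assert abs(avg(out.data).max() - avg(ref).max()) <= 0.1 * avg(ref).max()

    def test_short_calibration_rejected(self, rng):
        rec = EEGRecording(data=rng.standard_normal((24, 10000)))
        with pytest.raises(ValueError, match="calibration"):
            clean_bursts(rec, rng.standard_normal((24, 100)))


class TestRereference:
    def test_equal_channels_zero_out(self):
        rec = EEGRecording(data=np.full((24, 100), 3.3))
        assert np.abs(rereference(rec).data).max() < 1e-12

    def test_mastoid_mean_is_zero(self, rng):
        rec = EEGRecording(data=rng.standard_normal((24, 1000)))
        out = rereference(rec)
        i = [out.index_of("TP9"), out.index_of("TP10")]
        assert np.abs(out.data[i].mean(axis=0)).max() < 1e-12

    def test_idempotent(self, rng):
        rec = EEGRecording(data=rng.standard_normal((24, 1000)))
        once = rereference(rec)
        twice = rereference(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)


class TestInterpolation:
    def test_constant_topography_reproduced(self):
        good = tuple(c for c in CHANNELS if c != "Cz")
        M = interpolation_matrix(position_matrix(good), position_matrix(("Cz",)))
        assert M.sum() == pytest.approx(1.0, abs=1e-6)

    def test_leave_one_out_correlation(self, rng):
        data = _structured_background(rng, 4000, amp=4.0)
        missing = "Cz"
        good = tuple(c for c in CHANNELS if c != missing)
        rec = EEGRecording(
            data=data[[CHANNELS.index(c) for c in good]], channels=good)
        out = interpolate_channels(rec, [missing])
        r = np.corrcoef(out.data[out.index_of(missing)],
                        data[CHANNELS.index(missing)])[0, 1]
        assert r >= 0.95
        assert out.channels == CHANNELS

    def test_empty_missing_is_identity(self, rng):
        rec = EEGRecording(data=rng.standard_normal((24, 500)))
        out = interpolate_channels(rec, [])
        assert np.array_equal(out.data, rec.data)

    def test_too_few_channels_raises(self, rng):
        rec = EEGRecording(data=rng.standard_normal((3, 500)),
                           channels=("Fz", "Cz", "Pz"))
        with pytest.raises(ValueError, match="4 good channels"):
            interpolate_channels(rec, ["CPz"])


class TestEpoching:
    def test_baseline_zero_mean(self, rng):
        rec = EEGRecording(data=rng.standard_normal((24, 50000)))
        es = epoch(rec, pd.DataFrame({"time_s": [10.0, 20.0, 50.0]}))
        bmask = (es.times_ms > -100) & (es.times_ms <= 0)
        assert np.abs(es.epochs[:, :, bmask].mean(axis=2)).max() < 1e-12

    def test_boundary_events_dropped_with_reason(self, rng):
        rec = EEGRecording(data=rng.standard_normal((24, 5000)))
        es = epoch(rec, pd.DataFrame({"time_s": [0.1, 5.0, 9.9]}))
        assert len(es) == 1
        assert len(es.drop_log) == 2
        assert all("outside" in reason for _, reason in es.drop_log)

    def test_count_matches_brute_force(self, rng):
        rec = EEGRecording(data=rng.standard_normal((24, 100000)))
        times = rng.uniform(-1, 201, 60)
        es = epoch(rec, pd.DataFrame({"time_s": times}))
        lo, hi = -0.5, 1.5
        expected = sum(1 for t in times if t + lo > 0 and t + hi < 200.0 - 1 / 500)
        assert len(es) == expected
        assert len(es) + len(es.drop_log) == 60

    def test_window_is_half_open(self, rng):
        rec = EEGRecording(data=rng.standard_normal((24, 50000)))
        es = epoch(rec, pd.DataFrame({"time_s": [10.0]}))
        assert es.epochs.shape[2] == 1000
        assert es.times_ms[0] == pytest.approx(-498.0)
        assert es.times_ms[-1] == pytest.approx(1500.0)

    def test_epochs_overlapping_gap_dropped(self, rng):
        from wordbyword.synthetic_session import inject_packet_loss

        rec = EEGRecording(data=rng.standard_normal((24, 50000)).astype(np.float32))
        lossy, _ = inject_packet_loss(rec, [(50.0, 0.1)])
        es = epoch(lossy, pd.DataFrame({"time_s": [20.0, 49.9, 80.0]}))
        assert len(es) == 2
        assert any("gap" in reason for _, reason in es.drop_log)


class TestRejection:
    def _set(self, cube):
        return EpochSet(
            epochs=cube, labels=pd.DataFrame({"i": range(len(cube))}),
            times_ms=np.arange(cube.shape[2], dtype=float), rate=500.0,
            channels=CHANNELS,
        )

    def test_identical_epochs_none_rejected(self):
        out = reject_3sd(self._set(np.ones((10, 24, 100))))
        assert len(out) == 10

    def test_single_outlier_rejected(self, rng):
        cube = rng.standard_normal((50, 24, 100))
        cube[17] *= 100
        out = reject_3sd(self._set(cube))
        assert sorted(set(range(50)) - set(out.labels["i"])) == [17]

    def test_decisions_match_brute_force(self, rng):
        cube = rng.standard_normal((40, 24, 100)) * \
            rng.uniform(0.5, 4.0, size=(40, 1, 1))
        out = reject_3sd(self._set(cube))
        stat = np.abs(cube).max(axis=(1, 2))
        keep = stat <= stat.mean() + 3 * stat.std()
        assert sorted(out.labels["i"]) == sorted(np.flatnonzero(keep))
        assert np.array_equal(epoch_deviance(cube), stat)

    def test_too_few_epochs_raises(self, rng):
        with pytest.raises(ValueError, match="5"):
            reject_3sd(self._set(rng.standard_normal((3, 24, 100))))


class TestMatchCounts:
    def _set(self, n, rng):
        return EpochSet(
            epochs=rng.standard_normal((n, 24, 50)),
            labels=pd.DataFrame({"i": range(n)}),
            times_ms=np.arange(50.0), rate=500.0, channels=CHANNELS,
        )

    def test_equal_counts_identity(self, rng):
        a, b = self._set(10, rng), self._set(10, rng)
        ra, rb = match_counts(a, b, seed=0)
        assert len(ra) == len(rb) == 10
        assert np.array_equal(ra.epochs, a.epochs)

    def test_80_vs_40_subsampled_to_40(self, rng):
        a, b = self._set(80, rng), self._set(40, rng)
        ra, rb = match_counts(a, b, seed=0)
        assert len(ra) == len(rb) == 40
        assert list(ra.labels["i"]) == sorted(ra.labels["i"])  # order kept

    def test_seeded_determinism(self, rng):
        a, b = self._set(80, rng), self._set(40, rng)
        r1, _ = match_counts(a, b, seed=9)
        r2, _ = match_counts(a, b, seed=9)
        assert list(r1.labels["i"]) == list(r2.labels["i"])
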