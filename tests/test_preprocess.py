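"""Preprocessing: filtering, channel hygiene, referencing, epoching, subsampling."""

import numpy as np
import pytest

from mmncoh import EEGRecording, Epochs
from mmncoh import preprocess as pre
from mmncoh.preprocess import InsufficientTrialsError


def make_recording(montage, data=None, fs=250.0, duration_s=20.0, seed=0):
    rng = np.random.default_rng(seed)
    if data is None:
        data = 10.0 * rng.standard_normal((montage.n_channels, int(duration_s * fs)))
    return EEGRecording(data=data, montage=montage, fs_hz=fs)


class TestBandpass:
    def test_passband_preserved(self, montage):
        fs = 250.0
        t = np.arange(int(10 * fs)) / fs
        rec = make_recording(montage, data=np.tile(np.sin(2 * np.pi * 10 * t), (32, 1)), fs=fs)
        out = pre.bandpass(rec, 1, 30)
        mid = slice(int(2 * fs), int(8 * fs))  # avoid edges
        assert np.abs(out.data[0, mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated_24db(self, montage):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        rec = make_recording(montage, data=np.tile(np.sin(2 * np.pi * 60 * t), (32, 1)), fs=fs)
        out = pre.bandpass(rec, 1, 30)
        mid = slice(int(2 * fs), int(8 * fs))
        atten_db = -20 * np.log10(np.abs(out.data[0, mid]).max())
        assert atten_db >= 24.0  # one octave above the 30 Hz edge

    def test_dc_removed(self, montage):
        rec = make_recording(montage, data=np.full((32, 5000), 42.0), fs=250.0)
        out = pre.bandpass(rec, 1, 30)
        assert np.abs(out.data.mean()) < 1e-6

    def test_band_outside_nyquist_rejected(self, montage):
        rec = make_recording(montage, fs=100.0, duration_s=5)
        with pytest.raises(ValueError):
            pre.bandpass(rec, 1, 60)


class TestBadChannels:
    def test_flatline_flagged(self, montage):
        rec = make_recording(montage, seed=1)
        rec.data[montage.index("T7")] = 0.0
        assert pre.detect_bad_channels(rec) == {"T7"}

    def test_high_variance_flagged(self, montage):
        rec = make_recording(montage, seed=2)
        rec.data[montage.index("P3")] *= 100.0
        assert "P3" in pre.detect_bad_channels(rec)

    def test_homogeneous_channels_clean(self, montage):
        flagged = sum(bool(pre.detect_bad_channels(make_recording(montage, seed=s)))
                      for s in range(20))
        assert flagged <= 1  # false positives rare at z > 5


class TestMatchChannels:
    def test_set_union_removed(self, montage):
        good = pre.match_channels({"T7"}, {"P3"}, montage)
        assert set(montage.labels) - set(good) == {"T7", "P3"}

    def test_empty_sets_keep_all(self, montage):
        assert pre.match_channels(set(), set(), montage) == montage.labels

    def test_symmetric_and_idempotent(self, montage):
        a, b = {"T7", "Fz"}, {"P3"}
        ab = pre.match_channels(a, b, montage)
        ba = pre.match_channels(b, a, montage)
        assert ab == ba
        again = pre.match_channels(set(montage.labels) - set(ab), set(), montage)
        assert again == ab

    def test_too_few_good_channels(self, montage):
        with pytest.raises(ValueError):
            pre.match_channels(set(montage.labels[:-1]), set(), montage)


class TestRereference:
    def test_average_of_good_zero_mean(self, montage):
        rec = make_recording(montage, seed=3)
        rec.bads = {"T7"}
        out = pre.rereference(rec, "average_of_good")
        good_idx = [i for i, lab in enumerate(montage.labels) if lab != "T7"]
        assert np.allclose(out.data[good_idx].mean(axis=0), 0.0, atol=1e-10)

    def test_linked_mastoids_arithmetic(self, montage):
        rec = make_recording(montage, data=np.zeros((32, 100)))
        rec.data[montage.index("M1")] = 2.0
        rec.data[montage.index("M2")] = 4.0
        out = pre.rereference(rec, "linked_mastoids")
        fz = out.data[montage.index("Fz")]
        assert np.allclose(fz, -3.0)

    def test_zero_mastoids_identity(self, montage, rng):
        data = rng.standard_normal((32, 100))
        data[montage.index("M1")] = 0.0
        data[montage.index("M2")] = 0.0
        rec = make_recording(montage, data=data.copy())
        out = pre.rereference(rec, "linked_mastoids")
        assert np.allclose(out.data, data)

    def test_missing_mastoids_rejected(self, montage):
        sub = montage.subset([lab for lab in montage.labels if lab not in ("M1", "M2")])
        rec = EEGRecording(data=np.zeros((sub.n_channels, 10)), montage=sub, fs_hz=100.0)
        with pytest.raises(ValueError, match="M1"):
            pre.rereference(rec, "linked_mastoids")

    def test_works_on_epochs_too(self, montage, rng):
        ep = Epochs(data=rng.standard_normal((4, 32, 50)), montage=montage,
                    fs_hz=100.0, tmin_s=0.0, labels=np.array(["standard"] * 4, dtype=object))
        out = pre.rereference(ep, "average_of_good")
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-10)


class TestInterpolateBad:
    def test_neighbor_average(self, montage):
        rec = make_recording(montage, data=np.zeros((32, 50)))
        neighbors = montage.neighbors["FCz"]
        for i, lab in enumerate(neighbors):
            rec.data[montage.index(lab)] = float(i)
        rec.data[montage.index("FCz")] = 999.0
        out = pre.interpolate_bad(rec, {"FCz"})
        expected = np.mean([float(i) for i in range(len(neighbors))])
        assert np.allclose(out.data[montage.index("FCz")], expected)

    def test_identical_neighbors_reproduced(self, montage, rng):
        rec = make_recording(montage, data=np.zeros((32, 50)))
        sig = rng.standard_normal(50)
        for lab in montage.neighbors["Cz"]:
            rec.data[montage.index(lab)] = sig
        rec.data[montage.index("Cz")] = 1e6
        out = pre.interpolate_bad(rec, {"Cz"})
        assert np.allclose(out.data[montage.index("Cz")], sig)

    def test_empty_bad_is_identity(self, montage):
        rec = make_recording(montage, seed=4)
        out = pre.interpolate_bad(rec, set())
        assert out is rec

    def test_all_bad_rejected(self, montage):
        rec = make_recording(montage, seed=5)
        with pytest.raises(ValueError):
            pre.interpolate_bad(rec, set(montage.labels))


class TestEpochingAndRejection:
    def test_clean_data_no_rejections(self, montage):
        rec = make_recording(montage, seed=6)  # SD 10 uV, well within thresholds
        ep = pre.epoch_resting(rec)
        assert ep.rejection_log["n_rejected"] == 0
        assert ep.n_trials == 10  # 20 s / 2 s

    def test_spike_epoch_dropped(self, montage):
        rec = make_recording(montage, seed=7)
        rec.data[5, 1100] = 500.0  # inside epoch 2
        ep = pre.epoch_resting(rec)
        assert ep.rejection_log["dropped"] == [2]
        assert ep.n_trials == 9

    def test_injected_artifacts_counted(self, montage, rng):
        rec = make_recording(montage, duration_s=200, seed=8)
        bad = rng.choice(100, size=10, replace=False)
        for b in bad:
            rec.data[0, b * 500 + 10] = 300.0
        ep = pre.epoch_resting(rec)
        assert ep.n_trials == 90
        assert ep.rejection_log["n_rejected"] == 10

    def test_rejection_monotone_in_threshold(self, montage):
        rng = np.random.default_rng(9)
        fs = 250.0
        data = 5.0 * rng.standard_normal((montage.n_channels, int(60 * fs)))
        # one spike per epoch index 0..9 with amplitudes 30..210 uV
        for i, amp in enumerate(range(30, 211, 20)):
            data[3, i * 500 + 100] = float(amp)
        rec = EEGRecording(data=data, montage=montage, fs_hz=fs)
        strict = pre.epoch_resting(rec, abs_threshold_uv=50, pp_threshold_uv=80)
        loose = pre.epoch_resting(rec, abs_threshold_uv=100, pp_threshold_uv=150)
        assert strict.n_trials < loose.n_trials < 30
        assert set(strict.rejection_log["dropped"]) >= set(loose.rejection_log["dropped"])

    def test_stimulus_locked_baseline_correction(self, montage):
        fs = 500.0
        rec = make_recording(montage, data=np.full((32, 5000), 7.0), fs=fs)
        events = [(1000, "standard"), (2000, "duration")]
        ep = pre.epoch_stimulus_locked(rec, events, window_ms=(-100, 500),
                                       baseline_ms=(-100, 0))
        # constant offset removed by baseline subtraction
        assert np.allclose(ep.data, 0.0)
        assert list(ep.labels) == ["standard", "duration"]
        assert ep.tmin_s == pytest.approx(-0.1)

    def test_edge_events_skipped(self, montage):
        rec = make_recording(montage, fs=500.0, duration_s=4, seed=10)
        ep = pre.epoch_stimulus_locked(rec, [(10, "standard"), (1000, "standard")],
                                       window_ms=(-100, 500))
        assert ep.n_trials == 1
        assert ep.rejection_log["skipped_onsets"] == [10]

    def test_zero_survivors_is_error(self, montage):
        rec = make_recording(montage, seed=11)
        rec.data += 1e4
        rec2 = rec.copy_with(data=rec.data - rec.data.mean())  # keep mean ~0 but huge pp
        rec2.data *= 1e3
        with pytest.raises(ValueError, match="survive"):
            pre.epoch_resting(rec2)


class TestSubsample:
    def make_epochs(self, montage, n=100):
        rng = np.random.default_rng(0)
        return Epochs(data=rng.standard_normal((n, 32, 20)), montage=montage,
                      fs_hz=100.0, tmin_s=0.0,
                      labels=np.array(["standard"] * n, dtype=object))

    def test_deterministic_given_seed(self, montage):
        ep = self.make_epochs(montage)
        a = pre.subsample_trials(ep, 20, seed=5)
        b = pre.subsample_trials(ep, 20, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_full_sample_identity(self, montage):
        ep = self.make_epochs(montage, n=30)
        out = pre.subsample_trials(ep, 30, seed=1)
        assert np.array_equal(out.data, ep.data)  # order preserved

    def test_order_preserved(self, montage):
        ep = self.make_epochs(montage)
        ep.data[:, 0, 0] = np.arange(100)
        out = pre.subsample_trials(ep, 50, seed=2)
        picked = out.data[:, 0, 0]
        assert np.all(np.diff(picked) > 0)

    def test_insufficient_trials_reports_count(self, montage):
        ep = self.make_epochs(montage, n=40)
        with pytest.raises(InsufficientTrialsError, match="40") as exc:
            pre.subsample_trials(ep, 50, seed=0)
        assert exc.value.available == 40 and exc.value.requested == 50


def test_filter_then_epoch_matches_epoch_then_trim(montage):
    """Edge effects of filtfilt stay confined near the recording boundaries."""
    rec = make_recording(montage, duration_s=40, fs=250.0, seed=12)
    filtered = pre.bandpass(rec, 1, 30)
    # interior epochs cut after filtering equal filtering a long interior segment
    interior = rec.copy_with(data=rec.data[:, : 30 * 250])
    f2 = pre.bandpass(interior, 1, 30)
    a = filtered.data[:, 10 * 250: 20 * 250]
    b = f2.data[:, 10 * 250: 20 * 250]
    assert np.allclose(a, b, atol=1e-6 * np.abs(a).max())


def test_derive_seed_stable_and_in_range():
    s1 = pre.derive_seed(1, "S001", "pre", "coherence")
    s2 = pre.derive_seed(1, "S001", "pre", "coherence")
    s3 = pre.derive_seed(1, "S001", "post", "coherence")
    assert s1 == s2 != s3
    assert 0 <= s1 < 2**31
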