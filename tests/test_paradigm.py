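"""Stimulus-sequence structure and tone-synthesis physics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from mmncoh import paradigm as par
from mmncoh.paradigm import DeviantKind, StimulusSpec


# ---------------------------------------------------------------------------
# Optimum-1 sequence

class TestOptimum1:
    def test_event_counts(self):
        seq = par.generate_optimum1_sequence(seed=1)
        assert len(seq) == 1845
        fam = seq.family_counts()  # excludes formation tones
        assert fam["standard"] == 900
        for family in par.OPTIMUM1_FAMILIES:
            assert fam[family] == 180

    def test_formation_runs_open_each_block(self):
        seq = par.generate_optimum1_sequence(seed=7)
        for block in range(3):
            evs = [e for e in seq.events if e.block == block]
            assert len(evs) == 615
            assert all(e.kind is DeviantKind.STANDARD and e.is_formation
                       for e in evs[:15])
            assert not any(e.is_formation for e in evs[15:])

    def test_alternation_and_soa_grid(self):
        seq = par.generate_optimum1_sequence(seed=3)
        for block in range(3):
            evs = [e for e in seq.events if e.block == block]
            onsets = np.array([e.onset_s for e in evs])
            assert np.allclose(np.diff(onsets), 0.5)
            # every second non-formation tone is a standard
            tail = evs[15:]
            assert all(e.kind is DeviantKind.STANDARD for e in tail[1::2])
            assert all(e.kind is not DeviantKind.STANDARD for e in tail[0::2])
            # block spans 15 formation + 600 stimuli on the 0.5 s grid
            assert onsets[-1] == pytest.approx((615 - 1) * 0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 9, 41])
    def test_consecutive_deviants_differ_in_family(self, seed):
        seq = par.generate_optimum1_sequence(seed)
        for block in range(3):
            fams = [e.kind.family for e in seq.events
                    if e.block == block and e.kind is not DeviantKind.STANDARD]
            assert all(a != b for a, b in zip(fams, fams[1:]))

    def test_variant_split_within_families(self):
        counts = par.generate_optimum1_sequence(seed=5).counts()
        assert counts["frequency_up"] == counts["frequency_down"] == 90
        assert counts["intensity_up"] == counts["intensity_down"] == 90
        assert counts["location_left"] == counts["location_right"] == 90

    def test_deterministic_given_seed(self):
        a = par.generate_optimum1_sequence(123)
        b = par.generate_optimum1_sequence(123)
        assert [e.kind for e in a.events] == [e.kind for e in b.events]


# ---------------------------------------------------------------------------
# Memory-Trace sequence

class TestMemoryTrace:
    def test_event_counts(self):
        seq = par.generate_memorytrace_sequence(seed=1)
        assert len(seq) == 462
        fam = seq.family_counts(include_formation=True)
        assert fam["standard"] == 306
        assert fam["duration"] == fam["frequency"] == 78
        assert fam["standard"] / 462 == pytest.approx(0.662, abs=5e-4)

    @pytest.mark.parametrize("seed", [0, 4, 17])
    def test_standard_runs_between_deviants(self, seed):
        seq = par.generate_memorytrace_sequence(seed)
        for block in range(3):
            evs = [e for e in seq.events if e.block == block and not e.is_formation]
            runs, current = [], 0
            for e in evs:
                if e.kind is DeviantKind.STANDARD:
                    current += 1
                else:
                    runs.append(current)
                    current = 0
            assert current == 0  # blocks end on a deviant
            assert min(runs) >= 1 and max(runs) <= 3

    @pytest.mark.parametrize("seed", [0, 4, 17])
    def test_isi_structure(self, seed):
        """3 s before every deviant; other ISIs from {0.5, 1.5, 3} s."""
        seq = par.generate_memorytrace_sequence(seed)
        tone = par.TONE_DURATION_MS / 1000.0
        for block in range(3):
            evs = [e for e in seq.events if e.block == block]
            for prev, nxt in zip(evs, evs[1:]):
                isi = nxt.onset_s - prev.onset_s - tone
                if nxt.kind is not DeviantKind.STANDARD:
                    assert isi == pytest.approx(3.0)
                else:
                    assert min(abs(isi - x) for x in (0.5, 1.5, 3.0)) < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 50])
    def test_block_fits_six_minutes(self, seed):
        seq = par.generate_memorytrace_sequence(seed)
        for block in range(3):
            evs = [e for e in seq.events if e.block == block]
            assert evs[-1].onset_s + par.TONE_DURATION_MS / 1000.0 <= 360.0

    def test_formation_runs(self):
        seq = par.generate_memorytrace_sequence(seed=9)
        for block in range(3):
            evs = [e for e in seq.events if e.block == block]
            assert all(e.is_formation and e.kind is DeviantKind.STANDARD
                       for e in evs[:15])


@given(seed=hst.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=15, deadline=None)
def test_counts_invariant_across_seeds(seed):
    """Only ordering and ISI draws vary with the seed, never the composition."""
    opt = par.generate_optimum1_sequence(seed)
    mt = par.generate_memorytrace_sequence(seed)
    assert len(opt) == 1845 and len(mt) == 462
    assert opt.family_counts()["standard"] == 900
    assert mt.family_counts(include_formation=True)["standard"] == 306


# ---------------------------------------------------------------------------
# Tone synthesis

@pytest.fixture(scope="module")
def spec():
    return StimulusSpec()


@pytest.fixture(scope="module")
def standard(spec):
    return par.synthesize_stimulus(spec, DeviantKind.STANDARD)


class TestSynthesis:
    def test_standard_duration(self, standard, spec):
        # rendered length is exactly 75 ms; the envelope measurement loses the
        # zero-valued first/last ramp samples
        assert standard.duration_s * 1000 == pytest.approx(75.0)
        assert par.measured_duration_ms(standard) == pytest.approx(75.0, abs=0.1)

    def test_duration_deviant_50ms_shorter(self, spec):
        wave = par.synthesize_stimulus(spec, DeviantKind.DURATION)
        assert wave.duration_s * 1000 == pytest.approx(25.0)
        assert par.measured_duration_ms(wave) == pytest.approx(25.0, abs=0.1)

    def test_frequency_deviant_partials(self, spec):
        up = par.synthesize_stimulus(spec, DeviantKind.FREQUENCY_UP)
        down = par.synthesize_stimulus(spec, DeviantKind.FREQUENCY_DOWN)
        assert par.spectral_peaks_hz(up) == pytest.approx([550, 1100, 1650], abs=2.0)
        assert par.spectral_peaks_hz(down) == pytest.approx([450, 900, 1350], abs=2.0)

    def test_partial_levels(self, standard):
        assert par.partial_level_db(standard, 1000, 500) == pytest.approx(-3.0, abs=0.2)
        assert par.partial_level_db(standard, 1500, 500) == pytest.approx(-6.0, abs=0.2)

    @pytest.mark.parametrize("kind,delta", [(DeviantKind.INTENSITY_UP, 10.0),
                                            (DeviantKind.INTENSITY_DOWN, -10.0)])
    def test_intensity_step(self, spec, standard, kind, delta):
        wave = par.synthesize_stimulus(spec, kind)
        assert par.rms_db_difference(wave, standard) == pytest.approx(delta, abs=0.1)

    def test_gap_deviant_has_silent_core(self, spec, standard):
        wave = par.synthesize_stimulus(spec, DeviantKind.GAP)
        fs = spec.sample_rate_hz
        n = wave.n_samples
        n_gap = int(round(7e-3 * fs))
        n_edge = int(round(1e-3 * fs))
        start = (n - n_gap) // 2
        core = wave.left[start + n_edge: start + n_gap - n_edge]
        assert np.abs(core).max() == 0.0
        # total duration unchanged
        assert par.measured_duration_ms(wave) == pytest.approx(75.0, abs=0.1)

    @pytest.mark.parametrize("kind", [DeviantKind.LOCATION_LEFT, DeviantKind.LOCATION_RIGHT])
    def test_itd_800us(self, spec, kind):
        wave = par.synthesize_stimulus(spec, kind)
        assert par.interaural_lag_us(wave) == pytest.approx(800.0, abs=1e-6)
        lead, lag = ((wave.left, wave.right) if kind is DeviantKind.LOCATION_LEFT
                     else (wave.right, wave.left))
        d = int(round(800e-6 * spec.sample_rate_hz))
        assert np.allclose(lag[d:], lead[:-d])

    def test_peak_never_clips(self, spec):
        for kind in DeviantKind:
            wave = par.synthesize_stimulus(spec, kind)
            assert max(np.abs(wave.left).max(), np.abs(wave.right).max()) <= 1.0

    def test_non_integer_itd_rejected_unless_fractional(self):
        spec44 = StimulusSpec(sample_rate_hz=44100)
        with pytest.raises(ValueError, match="fractional_delay"):
            par.synthesize_stimulus(spec44, DeviantKind.LOCATION_LEFT)
        wave = par.synthesize_stimulus(spec44, DeviantKind.LOCATION_LEFT,
                                       fractional_delay=True)
        # integer-lag cross-correlation resolves the delay to within one sample
        assert par.interaural_lag_us(wave) == pytest.approx(800.0, abs=1e6 / 44100)

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            StimulusSpec(partial_freqs_hz=(500, 500, 1500))
        with pytest.raises(ValueError):
            StimulusSpec(duration_ms=8.0)
        with pytest.raises(ValueError):
            StimulusSpec(sample_rate_hz=2000.0)

    def test_wav_roundtrip(self, standard, tmp_path):
        from scipy.io import wavfile

        path = tmp_path / "standard.wav"
        standard.to_wav(path)
        fs, data = wavfile.read(path)
        assert fs == 50000 and data.shape == (standard.n_samples, 2)
        assert np.allclose(data[:, 0], standard.left, atol=1e-7)
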