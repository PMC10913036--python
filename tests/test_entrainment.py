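import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oscillotrack import (
    DegenerateInputError,
    InvalidParameterError,
    crosscorr,
    narrowband_phase,
    peak_plv,
    plv,
    plv_spectrum,
    stimulus_envelope,
)
from oscillotrack.entrainment import PLVSpectrum

FS = 500.0


class TestEnvelope:
    def test_tone_envelope_is_flat_at_tone_amplitude(self):
        fs_audio = 8000.0
        t = np.arange(int(3 * fs_audio)) / fs_audio
        audio = 2.0 * np.sin(2 * np.pi * 10.0 * t)
        env = stimulus_envelope(audio, fs_audio, FS)
        core = env[int(0.25 * FS) : -int(0.25 * FS)]
        assert np.all(np.abs(core - 2.0) < 0.04)  # < 2% ripple

    def test_output_length_matches_resampling_arithmetic(self):
        audio = np.random.default_rng(0).standard_normal(int(2.5 * 8000))
        env = stimulus_envelope(audio, 8000.0, FS)
        assert abs(len(env) - round(2.5 * FS)) <= 1

    def test_zero_audio_gives_zero_envelope(self):
        env = stimulus_envelope(np.zeros(8000), 8000.0, FS)
        assert np.all(env == 0.0)
        assert np.all(stimulus_envelope(np.ones(500), FS, FS) >= 0)

    def test_audio_rate_below_target_rejected(self):
        with pytest.raises(InvalidParameterError):
            stimulus_envelope(np.zeros(100), 250.0, FS)


class TestNarrowbandPhase:
    def test_tone_phase_advances_at_carrier_rate(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        ph = narrowband_phase(x, FS, 5.0)
        inc = np.diff(np.unwrap(ph))[int(4 * FS) : -int(4 * FS)]
        assert np.all(np.abs(inc - 2 * np.pi * 5.0 / FS) < 1e-3)

    def test_phase_is_amplitude_invariant(self):
        x = np.random.default_rng(1).standard_normal(4000)
        assert np.allclose(narrowband_phase(x, FS, 4.5), narrowband_phase(10.0 * x, FS, 4.5))

    @pytest.mark.parametrize("fc", [0.3, 249.8])
    def test_band_outside_valid_range_rejected(self, fc):
        with pytest.raises(InvalidParameterError):
            narrowband_phase(np.zeros(1000), FS, fc)


class TestPLV:
    def test_identical_sequences_give_exactly_one(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 10_000)
        assert plv(theta, theta) == 1.0

    def test_constant_offset_gives_one(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 5000)
        assert plv(theta, theta + 1.234) == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            plv(np.zeros(10), np.zeros(11))

    @given(st.integers(0, 2**16))
    def test_plv_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        t1 = r.uniform(-np.pi, np.pi, 64)
        t2 = r.uniform(-np.pi, np.pi, 64)
        assert 0.0 <= plv(t1, t2) <= 1.0

    @given(st.integers(0, 2**16), st.floats(0.1, 100.0))
    def test_plv_invariant_to_scaling_raw_signals(self, seed, scale):
        r = np.random.default_rng(seed)
        x = r.standard_normal(3000)
        y = r.standard_normal(3000)
        p1 = plv(narrowband_phase(x, FS, 4.5), narrowband_phase(y, FS, 4.5))
        p2 = plv(narrowband_phase(scale * x, FS, 4.5), narrowband_phase(y, FS, 4.5))
        assert abs(p1 - p2) < 1e-9


class TestPLVSpectrum:
    def test_default_grid_has_97_center_frequencies(self, envelope_45):
        spec = plv_spectrum(envelope_45, envelope_45, FS)
        assert len(spec.center_freqs) == 97
        assert spec.center_freqs[0] == pytest.approx(1.1)
        assert spec.center_freqs[-1] == pytest.approx(29.9)

    def test_envelope_against_itself_is_unity_everywhere(self, envelope_45):
        spec = plv_spectrum(envelope_45, envelope_45, FS)
        assert np.all(spec.plv > 1.0 - 1e-9)

    def test_record_too_short_after_trimming_rejected(self):
        with pytest.raises(InvalidParameterError):
            plv_spectrum(np.zeros(1000), np.zeros(1000), FS)  # 2 s << 8 s trim


class TestPeakPLV:
    def _spec(self, freqs, vals):
        return PLVSpectrum(np.asarray(freqs), np.asarray(vals), 0.5)

    def test_windowed_argmax(self):
        spec = self._spec([4.1, 4.4, 4.7, 5.0], [0.2, 0.9, 0.5, 0.1])
        pk, pf = peak_plv(spec, 4.5)
        assert (pk, pf) == (0.9, 4.4)

    def test_flat_spectrum_ties_to_lowest_frequency(self):
        spec = self._spec([4.1, 4.4, 4.7, 5.0], [0.3, 0.3, 0.3, 0.3])
        _, pf = peak_plv(spec, 4.5)
        assert pf == 4.1

    def test_peak_outside_window_ignored(self):
        spec = self._spec([2.0, 4.4, 6.0], [0.99, 0.2, 0.98])
        pk, pf = peak_plv(spec, 4.5)
        assert (pk, pf) == (0.2, 4.4)

    def test_empty_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            peak_plv(self._spec([1.0, 2.0], [0.1, 0.2]), 10.0)


class TestCrossCorrelation:
    def test_autocorrelation_peak_at_zero_lag(self, rng):
        x = rng.standard_normal(5000)
        mx, lag = crosscorr(x, x, FS)
        assert mx == pytest.approx(1.0)
        assert lag == 0.0

    def test_recovers_known_delay(self, rng):
        x = rng.standard_normal(5000)
        d = 37
        y = np.roll(x, d)
        mx, lag = crosscorr(x, y, FS, max_lag=0.2)
        assert lag == pytest.approx(d / FS)
        assert mx > 0.9

    def test_independent_noise_has_small_maximum(self, rng):
        x = rng.standard_normal(15_000)
        y = rng.standard_normal(15_000)
        mx, _ = crosscorr(x, y, FS)
        assert mx < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            crosscorr(np.ones(1000), np.zeros(1000) + 2.0, FS)
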