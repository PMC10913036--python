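import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oscillotrack import (
    InvalidParameterError,
    OverlapError,
    DegenerateInputError,
    TrainSpec,
    build_train,
    diagnostics,
    draw_isis,
    rms_equalize,
    synthesize_click,
    synthesize_syllable,
)
from oscillotrack.stimgen import make_token


class TestTokens:
    @pytest.mark.parametrize(
        "fs,n_expected",
        [(48818.0, 5), (500.0, 1), (10000.0, 1), (96000.0, 10)],
    )
    def test_click_length_is_100us_rounded_with_floor_of_one(self, fs, n_expected):
        tok = synthesize_click(fs)
        assert len(tok.samples) == n_expected
        assert np.all(tok.samples == 1.0)

    def test_click_rejects_nonpositive_rate(self):
        with pytest.raises(InvalidParameterError):
            synthesize_click(0.0)

    def test_syllable_duration_and_normalization(self):
        tok = synthesize_syllable(48818.0, f0=120.0, seed=2)
        assert len(tok.samples) == 2929  # round(0.060 * 48818)
        assert np.max(np.abs(tok.samples)) <= 1.0 + 1e-12
        assert tok.samples[0] == 0.0  # edge ramp

    def test_syllable_deterministic_given_seed(self):
        a = synthesize_syllable(16000.0, seed=7).samples
        b = synthesize_syllable(16000.0, seed=7).samples
        assert np.array_equal(a, b)
        c = synthesize_syllable(16000.0, seed=8).samples
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("kwargs", [{"fs": 4000.0}, {"fs": 8000.0, "f0": 50.0},
                                        {"fs": 8000.0, "formants": (700.0, 1200.0, 5000.0)}])
    def test_syllable_parameter_validation(self, kwargs):
        with pytest.raises(InvalidParameterError):
            synthesize_syllable(**kwargs)


class TestISIs:
    def test_zero_jitter_is_exactly_periodic(self):
        isis = draw_isis(TrainSpec(rate=4.5, jitter=0.0, n_tokens=50, fs=8000.0, seed=1))
        assert np.all(isis == 1.0 / 4.5)
        assert np.ptp(isis) == 0.0  # exactly zero spread

    def test_mean_rate_preserved_under_maximal_jitter(self):
        isis = draw_isis(TrainSpec(rate=4.5, jitter=0.8, n_tokens=10_000, fs=8000.0, seed=3))
        assert abs(np.mean(isis) - 1.0 / 4.5) < 0.01 * (1.0 / 4.5)

    @given(jitter=st.floats(0.0, 0.8), seed=st.integers(0, 2**16))
    def test_support_matches_closed_form_endpoints(self, jitter, seed):
        spec = TrainSpec(rate=4.5, jitter=jitter, n_tokens=200, fs=8000.0, seed=seed)
        isis = draw_isis(spec)
        half = spec.nominal_isi / 2.0
        assert np.all(isis >= half * (2.0 - jitter) - 1e-12)
        assert np.all(isis <= half * (2.0 + jitter) + 1e-12)

    def test_jitter_at_or_above_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            TrainSpec(rate=4.5, jitter=1.0, n_tokens=10, fs=8000.0)


class TestBuildTrain:
    def test_total_duration_matches_onset_arithmetic(self):
        spec = TrainSpec(rate=2.1, jitter=0.0, n_tokens=1000, fs=8000.0, seed=0)
        train = build_train(synthesize_click(8000.0), spec)
        assert train.onsets[0] == 0.0
        assert abs(train.onsets[-1] - 999 / 2.1) < 1e-6
        assert len(train.isis) == len(train.onsets) - 1

    def test_zero_jitter_audio_is_exactly_periodic(self):
        # fs / rate is an integer here, so periodicity is sample-exact
        spec = TrainSpec(rate=4.5, jitter=0.0, n_tokens=30, fs=9000.0, seed=0)
        train = build_train(synthesize_click(9000.0), spec)
        period = round(9000.0 / 4.5)
        a = train.audio
        assert np.array_equal(a[: len(a) - period], a[period:])

    def test_token_longer_than_minimum_interval_rejected(self):
        spec = TrainSpec(rate=14.9, jitter=0.8, n_tokens=10, fs=16000.0, seed=0)
        with pytest.raises(OverlapError):
            build_train(synthesize_syllable(16000.0), spec)  # 60 ms > 40 ms min ISI

    def test_sampling_rate_mismatch_rejected(self):
        spec = TrainSpec(rate=4.5, jitter=0.0, n_tokens=10, fs=8000.0)
        with pytest.raises(InvalidParameterError):
            build_train(synthesize_click(16000.0), spec)


class TestRmsEqualize:
    def _train(self, kind, scale=1.0, fs=8000.0):
        import dataclasses

        spec = TrainSpec(rate=4.5, jitter=0.0, n_tokens=40, fs=fs, seed=1)
        tr = build_train(make_token(kind, fs), spec)
        return tr if scale == 1.0 else dataclasses.replace(tr, audio=tr.audio * scale)

    def test_single_train_unchanged(self):
        tr = self._train("click")
        (out,) = rms_equalize([tr])
        assert np.array_equal(out.audio, tr.audio)

    def test_click_and_syllable_rms_ratio_unity(self):
        trains = [self._train("click"), self._train("syllable")]
        out = rms_equalize(trains)
        rms = [np.sqrt(np.mean(t.audio**2)) for t in out]
        assert abs(rms[1] / rms[0] - 1.0) < 1e-9

    def test_scale_invariance(self):
        a = rms_equalize([self._train("click"), self._train("syllable")])
        b = rms_equalize([self._train("click"), self._train("syllable", scale=10.0)])
        assert np.allclose(a[1].audio, b[1].audio, rtol=1e-9, atol=1e-12)

    def test_silent_train_rejected(self):
        tr = self._train("click")
        silent = type(tr)(onsets=tr.onsets, isis=tr.isis, audio=np.zeros_like(tr.audio),
                          fs=tr.fs, spec=tr.spec, kind=tr.kind)
        with pytest.raises(DegenerateInputError):
            rms_equalize([tr, silent])


class TestDiagnostics:
    def test_acf_normalized_at_lag_zero(self, click_train_45):
        d = diagnostics(click_train_45, max_lag=0.75)
        assert d.acf[0] == pytest.approx(1.0)
        assert np.all(d.acf <= 1.0 + 1e-9)

    def test_periodic_train_first_acf_peak_at_nominal_period(self, click_train_45):
        d = diagnostics(click_train_45, max_lag=0.75)
        # nominal period 222.2 ms; lag bins are 2 ms at the 500 Hz envelope rate
        assert d.acf_first_peak_lag == pytest.approx(0.222, abs=0.002)

    def test_f0_energy_decreases_with_jitter(self):
        vals = []
        for j in (0.0, 0.2, 0.4, 0.6, 0.8):
            spec = TrainSpec(rate=4.5, jitter=j, n_tokens=1000, fs=8000.0, seed=3)
            train = build_train(synthesize_click(8000.0), spec)
            vals.append(diagnostics(train, max_lag=0.75).f0_energy)
        assert np.all(np.diff(vals) <= 0)

    def test_envelope_spectrum_peak_at_rate_for_periodic_train(self, click_train_45):
        d = diagnostics(click_train_45, max_lag=0.75)
        peak_freq = d.freqs[np.argmax(d.spectrum)]
        assert abs(peak_freq - 4.5) <= d.freqs[1] - d.freqs[0]

    def test_invalid_max_lag_rejected(self, click_train_45):
        with pytest.raises(InvalidParameterError):
            diagnostics(click_train_45, max_lag=0.0)
        with pytest.raises(InvalidParameterError):
            diagnostics(click_train_45, max_lag=100.0)
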