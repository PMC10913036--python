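"""Band-scanned phase-locking value (PLV) and cross-correlation control.

The central statistic is the phase-locking value between the instantaneous
Hilbert phases of two narrowband signals,

    PLV = (1/T) | sum_t exp(i [theta1(t) - theta2(t)]) |,

which is 0 for a random phase relation and 1 for perfect synchrony.  To map
entrainment as a function of frequency, both the cortical source waveform
and the stimulus amplitude envelope are band-pass filtered (+/- 0.5 Hz)
around each center frequency of a scan grid (default 1.1--30 Hz in 0.3 Hz
steps), phases are extracted, and PLV is computed per band.  The peak of
the resulting PLV spectrum within +/- 0.5 Hz of the nominal presentation
rate quantifies entrainment for one condition.  A normalized stimulus-to-
response cross-correlation serves as an amplitude-domain control.

Filtering is zero-phase (forward-backward 4th-order Butterworth) because
any group delay would masquerade as a phase offset; narrowband filters
ring, so edge transients (2/halfwidth seconds per side, 4 s at the default
0.5 Hz halfwidth) are trimmed before the PLV sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np
from scipy import signal

from .exceptions import DegenerateInputError, InvalidParameterError

#: Default PLV scan grid (Hz).
DEFAULT_FMIN = 1.1
DEFAULT_FMAX = 30.0
DEFAULT_STEP = 0.3
#: Half-width of each analysis band (Hz).
DEFAULT_HALFWIDTH = 0.5
#: Window around the nominal rate for peak extraction (Hz).
DEFAULT_PEAK_WINDOW = 0.5


@dataclass(frozen=True)
class PLVSpectrum:
    """PLV as a function of band center frequency for one (record, source)."""

    center_freqs: np.ndarray
    plv: np.ndarray
    band_halfwidth: float
    source_label: str = ""
    condition: str = ""


@dataclass(frozen=True)
class ConditionResult:
    """Peak PLV and cross-correlation summary for one design cell."""

    subject_id: str
    condition: str
    stimulus: str
    rate: float
    jitter: float
    source_label: str
    peak_plv: float
    peak_freq: float
    xcorr_max: float
    xcorr_lag: float


def stimulus_envelope(audio: np.ndarray, fs_audio: float, fs_target: float = 500.0) -> np.ndarray:
    """Full-band Hilbert envelope of ``audio`` resampled to ``fs_target``.

    The modulus of the analytic signal is anti-alias filtered and polyphase
    resampled; the result is clipped at zero (filter ripple can produce tiny
    negative excursions).  Output length is ``round(duration * fs_target)``
    within one sample.
    """
    if fs_audio < fs_target:
        raise InvalidParameterError(
            f"fs_audio ({fs_audio}) must be >= target rate ({fs_target})"
        )
    audio = np.asarray(audio, dtype=float)
    env = np.abs(signal.hilbert(audio))
    if fs_audio == fs_target:
        return env
    # Rational resampling ratio; fall back to rounding for non-integer rates.
    num, den = int(round(fs_target)), int(round(fs_audio))
    g = gcd(num, den)
    out = signal.resample_poly(env, num // g, den // g)
    return np.clip(out, 0.0, None)


def narrowband_phase(
    x: np.ndarray, fs: float, fc: float, halfwidth: float = DEFAULT_HALFWIDTH
) -> np.ndarray:
    """Instantaneous Hilbert phase of ``x`` band-passed to ``fc ± halfwidth``.

    Zero-phase (forward-backward) 4th-order Butterworth; phases are returned
    wrapped in (-pi, pi].  Amplitude scaling of ``x`` leaves phases unchanged.
    """
    if fc - halfwidth <= 0:
        raise InvalidParameterError(f"band [{fc - halfwidth}, {fc + halfwidth}] extends to <= 0 Hz")
    if fc + halfwidth >= fs / 2:
        raise InvalidParameterError(
            f"band edge {fc + halfwidth} Hz reaches Nyquist ({fs / 2} Hz)"
        )
    sos = signal.butter(4, [fc - halfwidth, fc + halfwidth], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, np.asarray(x, dtype=float))
    return np.angle(signal.hilbert(y))


def plv(theta1: np.ndarray, theta2: np.ndarray) -> float:
    """Phase-locking value of two phase sequences (radians)."""
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    if theta1.shape != theta2.shape:
        raise InvalidParameterError(
            f"phase sequences differ in shape: {theta1.shape} vs {theta2.shape}"
        )
    if theta1.size < 2:
        raise InvalidParameterError("need at least two phase samples")
    return float(np.abs(np.mean(np.exp(1j * (theta1 - theta2)))))


def plv_spectrum(
    source_wave: np.ndarray,
    envelope: np.ndarray,
    fs: float,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    step: float = DEFAULT_STEP,
    halfwidth: float = DEFAULT_HALFWIDTH,
    source_label: str = "",
    condition: str = "",
) -> PLVSpectrum:
    """Scan PLV between a source waveform and the stimulus envelope.

    Both signals are filtered identically per center frequency; edge
    transients of 2/halfwidth seconds are trimmed from each side before the
    PLV sum.
    """
    source_wave = np.asarray(source_wave, dtype=float)
    envelope = np.asarray(envelope, dtype=float)
    if source_wave.shape != envelope.shape:
        raise InvalidParameterError("source and envelope must have equal length")
    n_freqs = int(np.floor((fmax - fmin) / step + 1e-9)) + 1
    freqs = fmin + step * np.arange(n_freqs)
    trim = int(round((2.0 / halfwidth) * fs))
    if len(source_wave) - 2 * trim < 2:
        raise InvalidParameterError(
            f"record too short: {len(source_wave)} samples leaves nothing after "
            f"trimming {trim} per side"
        )
    sl = slice(trim, len(source_wave) - trim)
    values = np.empty(n_freqs)
    for i, fc in enumerate(freqs):
        th1 = narrowband_phase(source_wave, fs, fc, halfwidth)
        th2 = narrowband_phase(envelope, fs, fc, halfwidth)
        values[i] = plv(th1[sl], th2[sl])
    return PLVSpectrum(
        center_freqs=freqs,
        plv=values,
        band_halfwidth=halfwidth,
        source_label=source_label,
        condition=condition,
    )


def peak_plv(
    spectrum: PLVSpectrum, nominal_rate: float, window: float = DEFAULT_PEAK_WINDOW
) -> tuple[float, float]:
    """Peak PLV within ``nominal_rate ± window``; ties go to the lowest frequency.

    Returns ``(peak_plv, peak_freq)``.
    """
    mask = np.abs(spectrum.center_freqs - nominal_rate) <= window + 1e-9
    if not np.any(mask):
        raise InvalidParameterError(
            f"no scan frequency within ±{window} Hz of {nominal_rate} Hz"
        )
    freqs = spectrum.center_freqs[mask]
    vals = spectrum.plv[mask]
    i = int(np.argmax(vals))  # argmax returns the first (lowest-frequency) maximum
    return float(vals[i]), float(freqs[i])


def crosscorr(
    envelope: np.ndarray, source_wave: np.ndarray, fs: float, max_lag: float = 0.5
) -> tuple[float, float]:
    """Normalized stimulus-to-response cross-correlation.

    Returns the maximum absolute correlation within ``±max_lag`` seconds and
    its lag.  A positive lag means the source waveform lags the envelope.
    The absolute value is taken because source polarity is sign-ambiguous.
    """
    x = np.asarray(envelope, dtype=float)
    y = np.asarray(source_wave, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("signals must have equal length")
    n = len(x)
    if max_lag >= n / fs / 2:
        raise InvalidParameterError("max_lag must be less than half the record duration")
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt(np.sum(x**2) * np.sum(y**2))
    if denom == 0:
        raise DegenerateInputError("zero-variance input to crosscorr")
    c = signal.correlate(y, x, mode="full") / denom
    lags = np.arange(-(n - 1), n) / fs
    keep = np.abs(lags) <= max_lag + 1e-12
    c = c[keep]
    lags = lags[keep]
    i = int(np.argmax(np.abs(c)))
    return float(np.abs(c[i])), float(lags[i])
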