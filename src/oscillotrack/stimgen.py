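"""Auditory token-train synthesis and acoustic diagnostics.

Builds the two stimulus classes used throughout the package -- broadband
clicks (100 µs rectangular pulses) and a 60 ms consonant--vowel syllable
token resembling /ba/ -- and strings them into trains whose presentation
rate and periodicity (jitter) are parametric.  Jitter perturbs half of the
nominal inter-stimulus interval with a uniform draw, so the mean rate is
preserved while periodicity degrades:

    ISI = ISI_nom/2 + U,  U ~ Uniform[ISI_nom/2 (1 - j), ISI_nom/2 (1 + j)]

with j in [0, 1).  ``diagnostics`` computes the descriptive acoustics of a
train (ISI distribution, envelope autocorrelation, envelope spectrum) used
to verify that jitter blurs periodicity without changing mean rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .exceptions import DegenerateInputError, InvalidParameterError, OverlapError

#: Presentation rates (Hz) of the rate experiment.
RATES = (2.1, 3.3, 4.5, 8.5, 14.9)
#: Jitter fractions of the periodicity experiment (applied at 4.5 Hz).
JITTERS = (0.0, 0.2, 0.4, 0.6, 0.8)
#: Default audio sampling rate (Hz).
DEFAULT_FS_AUDIO = 48818.0
#: Click duration in seconds (100 microseconds).
CLICK_DURATION = 100e-6
#: Syllable token duration in seconds.
SYLLABLE_DURATION = 0.060


@dataclass(frozen=True)
class TokenWaveform:
    """A single stimulus token."""

    samples: np.ndarray
    fs: float
    kind: str  # "click" or "syllable"

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class TrainSpec:
    """Parameters of one rate x jitter stimulus train."""

    rate: float
    jitter: float
    n_tokens: int
    fs: float = DEFAULT_FS_AUDIO
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidParameterError(f"rate must be positive, got {self.rate}")
        if not 0.0 <= self.jitter < 1.0:
            raise InvalidParameterError(
                f"jitter must be in [0, 1) to keep intervals positive, got {self.jitter}"
            )
        if self.n_tokens < 1:
            raise InvalidParameterError("n_tokens must be >= 1")
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")

    @property
    def nominal_isi(self) -> float:
        return 1.0 / self.rate


@dataclass(frozen=True)
class StimulusTrain:
    """A realized token train: onsets, intervals, and rendered audio."""

    onsets: np.ndarray  # token onset times (s), strictly increasing, onsets[0] = 0
    isis: np.ndarray  # onset-to-onset intervals (s), len = len(onsets) - 1
    audio: np.ndarray
    fs: float
    spec: TrainSpec
    kind: str = "click"

    @property
    def duration(self) -> float:
        return len(self.audio) / self.fs


@dataclass(frozen=True)
class AcousticDiagnostics:
    """Descriptive acoustics of one train (ISI histogram, envelope ACF, spectrum)."""

    isi_mean: float
    isi_hist: tuple[np.ndarray, np.ndarray]  # (counts, bin_edges)
    lags: np.ndarray  # s
    acf: np.ndarray  # normalized to 1 at lag 0
    acf_first_peak_lag: float  # s
    freqs: np.ndarray  # Hz
    spectrum: np.ndarray  # envelope magnitude spectrum
    f0_energy: float  # spectrum magnitude at the bin nearest the nominal rate


def synthesize_click(fs: float) -> TokenWaveform:
    """Rectangular 100 µs unit-amplitude click; at least one sample long."""
    if fs <= 0:
        raise InvalidParameterError(f"fs must be positive, got {fs}")
    n = max(1, int(round(CLICK_DURATION * fs)))
    return TokenWaveform(samples=np.ones(n), fs=float(fs), kind="click")


def synthesize_syllable(
    fs: float,
    f0: float = 120.0,
    formants: Sequence[float] = (700.0, 1200.0, 2500.0),
    seed: int = 0,
) -> TokenWaveform:
    """Source--filter synthesis of a 60 ms /ba/-like consonant--vowel token.

    A brief low-amplitude burst is followed by a voiced segment: a glottal
    impulse train at ``f0`` driven through cascaded second-order resonators.
    The first formant rises during the initial transition (the acoustic
    signature of a labial stop release into /a/).  Edges are ramped to zero
    and the peak amplitude is normalized to 1.  Deterministic given ``seed``.
    """
    if fs < 8000:
        raise InvalidParameterError(f"fs must be >= 8000 Hz for the syllable token, got {fs}")
    if not 80.0 <= f0 <= 300.0:
        raise InvalidParameterError(f"f0 must lie in [80, 300] Hz, got {f0}")
    formants = tuple(float(f) for f in formants)
    if max(formants) >= fs / 2:
        raise InvalidParameterError(
            f"highest formant {max(formants)} Hz cannot be represented at fs={fs}"
        )

    rng = np.random.default_rng(seed)
    n = int(round(SYLLABLE_DURATION * fs))
    t = np.arange(n) / fs

    # Glottal source: impulse train at f0, weak during the 10 ms burst portion.
    source = np.zeros(n)
    pulse_idx = np.round(np.arange(0.0, SYLLABLE_DURATION, 1.0 / f0) * fs).astype(int)
    source[pulse_idx[pulse_idx < n]] = 1.0
    burst_len = int(round(0.005 * fs))
    burst = rng.standard_normal(burst_len) * 0.15
    source[:burst_len] += burst

    # Cascaded time-varying resonators.  F1 rises 300 Hz -> target over 30 ms.
    f1_target = formants[0]
    transition = np.clip(t / 0.030, 0.0, 1.0)
    f1_track = 300.0 + (f1_target - 300.0) * transition
    bandwidths = (90.0, 110.0, 170.0)

    y = source
    for fi, (f_nom, bw) in enumerate(zip(formants, bandwidths)):
        track = f1_track if fi == 0 else np.full(n, f_nom)
        y = _time_varying_resonator(y, track, bw, fs)

    # Edge ramps (5 ms raised cosine) and peak normalization.
    ramp = int(round(0.005 * fs))
    win = np.ones(n)
    edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    win[:ramp] = edge
    win[-ramp:] = edge[::-1]
    y = y * win
    peak = np.max(np.abs(y))
    if peak > 0:
        y = y / peak
    return TokenWaveform(samples=y, fs=float(fs), kind="syllable")


def _time_varying_resonator(x: np.ndarray, freq_track: np.ndarray, bw: float, fs: float) -> np.ndarray:
    """Second-order resonator whose center frequency follows ``freq_track``."""
    r = np.exp(-np.pi * bw / fs)
    theta = 2 * np.pi * freq_track / fs
    a1 = 2 * r * np.cos(theta)
    a2 = -r * r
    gain = (1 - r) * np.sqrt(1 - 2 * r * np.cos(2 * theta) + r * r)
    y = np.zeros_like(x)
    y1 = y2 = 0.0
    for i in range(len(x)):
        y[i] = gain[i] * x[i] + a1[i] * y1 + a2 * y2
        y2, y1 = y1, y[i]
    return y


def draw_isis(spec: TrainSpec) -> np.ndarray:
    """Draw the ``n_tokens - 1`` onset-to-onset intervals of a train.

    Each interval is a fixed half-period plus a uniformly jittered
    half-period, so the expected interval equals the nominal period for
    every jitter level.  Seeded and reproducible via ``spec.seed``.
    """
    half = spec.nominal_isi / 2.0
    lo = half * (1.0 - spec.jitter)
    hi = half * (1.0 + spec.jitter)
    rng = np.random.default_rng(spec.seed)
    n_intervals = spec.n_tokens - 1
    if spec.jitter == 0.0:
        # Degenerate uniform; bypass the rng for exact periodicity.
        rng.uniform(lo, hi, size=n_intervals)  # keep the stream position consistent
        return np.full(n_intervals, spec.nominal_isi)
    return half + rng.uniform(lo, hi, size=n_intervals)


def build_train(token: TokenWaveform, spec: TrainSpec) -> StimulusTrain:
    """Place copies of ``token`` at jittered onsets; first onset at t = 0."""
    if abs(token.fs - spec.fs) > 1e-9:
        raise InvalidParameterError(
            f"token fs ({token.fs}) must equal spec fs ({spec.fs})"
        )
    isis = draw_isis(spec)
    min_possible = spec.nominal_isi / 2.0 * (2.0 - spec.jitter)
    if token.duration >= min_possible:
        raise OverlapError(
            f"token duration {token.duration:.4f}s >= minimum possible interval "
            f"{min_possible:.4f}s at jitter={spec.jitter}"
        )
    onsets = np.concatenate([[0.0], np.cumsum(isis)])
    if len(isis):
        bad = np.flatnonzero(isis < token.duration)
        if bad.size:
            raise OverlapError(
                f"token duration {token.duration:.4f}s overlaps interval "
                f"{bad[0]} ({isis[bad[0]]:.4f}s)"
            )
    n_tok = len(token.samples)
    n_audio = int(round(onsets[-1] * spec.fs)) + n_tok
    audio = np.zeros(n_audio)
    for on in onsets:
        i0 = int(round(on * spec.fs))
        audio[i0 : i0 + n_tok] += token.samples
    return StimulusTrain(onsets=onsets, isis=isis, audio=audio, fs=spec.fs, spec=spec, kind=token.kind)


def rms_equalize(trains: Sequence[StimulusTrain]) -> list[StimulusTrain]:
    """Scale every train so all share the RMS amplitude of the first."""
    if len(trains) == 0:
        raise InvalidParameterError("need at least one train")
    rms = [float(np.sqrt(np.mean(tr.audio**2))) for tr in trains]
    for i, r in enumerate(rms):
        if r == 0.0:
            raise DegenerateInputError(f"train {i} is silent (RMS 0); cannot equalize")
    target = rms[0]
    out = []
    for tr, r in zip(trains, rms):
        out.append(
            StimulusTrain(
                onsets=tr.onsets,
                isis=tr.isis,
                audio=tr.audio * (target / r),
                fs=tr.fs,
                spec=tr.spec,
                kind=tr.kind,
            )
        )
    return out


def diagnostics(train: StimulusTrain, max_lag: float = 0.75, fs_env: float = 500.0) -> AcousticDiagnostics:
    """Acoustic diagnostics of one train.

    The autocorrelation is computed on the Hilbert envelope of the audio
    (downsampled to ``fs_env``) so click and syllable trains are directly
    comparable; lag 0 is normalized to 1.  The first local maximum at lags
    beyond half the nominal period is reported as the periodicity peak.  The
    magnitude spectrum of the (mean-removed) envelope is read at the bin
    nearest the nominal rate to give ``f0_energy``.
    """
    from .entrainment import stimulus_envelope  # local import: one-way dependency

    if max_lag <= 0:
        raise InvalidParameterError(f"max_lag must be positive, got {max_lag}")
    if train.duration <= 2 * max_lag:
        raise InvalidParameterError(
            f"train duration {train.duration:.2f}s must exceed 2 x max_lag ({2 * max_lag:.2f}s)"
        )
    env = stimulus_envelope(train.audio, train.fs, fs_env)
    env = env - env.mean()
    n = len(env)
    acf_full = signal.correlate(env, env, mode="full")[n - 1 :]
    acf_full = acf_full / acf_full[0]
    n_lag = min(n - 1, int(round(max_lag * fs_env)))
    acf = acf_full[: n_lag + 1]
    lags = np.arange(n_lag + 1) / fs_env

    half_period = 0.5 * train.spec.nominal_isi
    start = int(np.ceil(half_period * fs_env))
    search = acf[start:]
    # require relative prominence so resampling-filter ripple is not mistaken
    # for a periodicity peak
    prominence = 0.1 * float(np.ptp(search)) if search.size else 0.0
    peaks, _ = signal.find_peaks(search, prominence=prominence)
    if peaks.size == 0:
        first_peak_lag = float("nan")
    else:
        first_peak_lag = float(lags[start + peaks[0]])

    # Welch-averaged amplitude spectrum: segment averaging keeps the f0 read
    # stable even when jitter has spread most of the line energy into noise
    nperseg = min(n, 4096)
    freqs, psd = signal.welch(env, fs=fs_env, nperseg=nperseg)
    spectrum = np.sqrt(psd)
    f0_bin = int(np.argmin(np.abs(freqs - train.spec.rate)))

    counts, edges = np.histogram(train.isis, bins=30) if len(train.isis) else (np.array([]), np.array([]))
    return AcousticDiagnostics(
        isi_mean=float(np.mean(train.isis)) if len(train.isis) else float("nan"),
        isi_hist=(counts, edges),
        lags=lags,
        acf=acf,
        acf_first_peak_lag=first_peak_lag,
        freqs=freqs,
        spectrum=spectrum,
        f0_energy=float(spectrum[f0_bin]),
    )


def make_token(kind: str, fs: float, seed: int = 0) -> TokenWaveform:
    """Convenience dispatcher: ``kind`` is 'click' or 'syllable'."""
    if kind == "click":
        return synthesize_click(fs)
    if kind == "syllable":
        return synthesize_syllable(fs, seed=seed)
    raise InvalidParameterError(f"unknown token kind {kind!r}")
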