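"""Model/Results interface for cortico-acoustic entrainment analysis.

``EntrainmentModel`` fits one EEG record against its evoking stimulus
train: the scalp data are common-average referenced, projected to left and
right auditory-cortex source waveforms through the montage, a fixed-length
analysis segment is extracted, and the band-scanned phase-locking value
plus the cross-correlation control are computed per hemisphere.  The
returned ``EntrainmentResults`` carries the PLV spectra, per-source peak
estimates, their hemisphere-collapsed means, and a ``summary()`` table.

``CohortTrendModel`` fits group-level within-subject statistics to a tidy
cohort table of per-condition peak estimates (square-root transformed by
default): linear trends across jitter per stimulus class and paired
stimulus-domain contrasts per jitter level with Holm adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import entrainment, sourcespace, stats
from .exceptions import InvalidParameterError
from .sourcespace import SourceMontage
from .stimgen import StimulusTrain


class EntrainmentModel:
    """Entrainment of one EEG record to one stimulus train.

    Parameters
    ----------
    eeg : ndarray, channels x samples (µV)
    fs : float
        EEG sampling rate (Hz).
    train : StimulusTrain
        The evoking stimulus; its audio provides the envelope reference.
    montage : SourceMontage
        Leadfield used to reduce scalp channels to AC source waveforms.
    segment_start, segment_length : float
        Analysis window (s); default the first 30 s.
    fmin, fmax, step, halfwidth : float
        PLV scan grid and band half-width (Hz).
    peak_window : float
        Half-width (Hz) of the peak-extraction window around the rate.
    """

    def __init__(
        self,
        eeg: np.ndarray,
        fs: float,
        train: StimulusTrain,
        montage: SourceMontage,
        *,
        segment_start: float = 0.0,
        segment_length: float = 30.0,
        fmin: float = entrainment.DEFAULT_FMIN,
        fmax: float = entrainment.DEFAULT_FMAX,
        step: float = entrainment.DEFAULT_STEP,
        halfwidth: float = entrainment.DEFAULT_HALFWIDTH,
        peak_window: float = entrainment.DEFAULT_PEAK_WINDOW,
        xcorr_max_lag: float = 0.5,
        subject_id: str = "s00",
        condition: str | None = None,
    ) -> None:
        self.eeg = np.asarray(eeg, dtype=float)
        self.fs = float(fs)
        self.train = train
        self.montage = montage
        self.segment_start = segment_start
        self.segment_length = segment_length
        self.fmin, self.fmax, self.step = fmin, fmax, step
        self.halfwidth = halfwidth
        self.peak_window = peak_window
        self.xcorr_max_lag = xcorr_max_lag
        self.subject_id = subject_id
        self.condition = condition or f"{train.kind}_r{train.spec.rate}_j{int(round(train.spec.jitter * 100)):02d}"

    def fit(self) -> "EntrainmentResults":
        eeg = sourcespace.rereference_common_average(self.eeg)
        sources = sourcespace.apply_montage(eeg, self.montage, self.fs)
        segment = sourcespace.extract_segment(sources, self.segment_start, self.segment_length)

        env = entrainment.stimulus_envelope(self.train.audio, self.train.fs, self.fs)
        i0 = int(round(self.segment_start * self.fs))
        n = segment.n_samples
        if len(env) < i0 + n:
            env = np.pad(env, (0, i0 + n - len(env)), mode="edge")
        env = env[i0 : i0 + n]

        rate = self.train.spec.rate
        spectra, rows = [], []
        for k, label in enumerate(segment.labels):
            spec = entrainment.plv_spectrum(
                segment.currents[k], env, self.fs,
                self.fmin, self.fmax, self.step, self.halfwidth,
                source_label=label, condition=self.condition,
            )
            pk, pf = entrainment.peak_plv(spec, rate, self.peak_window)
            xc, lag = entrainment.crosscorr(env, segment.currents[k], self.fs, self.xcorr_max_lag)
            spectra.append(spec)
            rows.append(
                entrainment.ConditionResult(
                    subject_id=self.subject_id,
                    condition=self.condition,
                    stimulus=self.train.kind,
                    rate=rate,
                    jitter=self.train.spec.jitter,
                    source_label=label,
                    peak_plv=pk,
                    peak_freq=pf,
                    xcorr_max=xc,
                    xcorr_lag=lag,
                )
            )
        return EntrainmentResults(model=self, spectra=spectra, per_source=rows)


@dataclass
class EntrainmentResults:
    """Fit results: PLV spectra and peak/cross-correlation estimates."""

    model: EntrainmentModel
    spectra: list[entrainment.PLVSpectrum]
    per_source: list[entrainment.ConditionResult]

    @property
    def peak_plv(self) -> float:
        """Hemisphere-collapsed peak PLV (mean of L/R peaks)."""
        return float(np.mean([r.peak_plv for r in self.per_source]))

    @property
    def peak_freq(self) -> float:
        return float(np.mean([r.peak_freq for r in self.per_source]))

    @property
    def xcorr_max(self) -> float:
        return float(np.mean([r.xcorr_max for r in self.per_source]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-source results table."""
        return pd.DataFrame([vars(r) for r in self.per_source])

    def summary(self) -> str:
        lines = [
            "Entrainment fit",
            "=" * 64,
            f"subject: {self.model.subject_id}   condition: {self.model.condition}",
            f"stimulus: {self.model.train.kind}  rate: {self.model.train.spec.rate} Hz"
            f"  jitter: {self.model.train.spec.jitter * 100:.0f}%",
            f"segment: {self.model.segment_length:.0f} s @ {self.model.fs:.0f} Hz"
            f"   scan: {self.model.fmin}-{self.model.fmax} Hz (step {self.model.step})",
            "-" * 64,
            f"{'source':<24}{'peak PLV':>10}{'peak f (Hz)':>12}{'xcorr max':>10}{'lag (ms)':>8}",
        ]
        for r in self.per_source:
            lines.append(
                f"{r.source_label:<24}{r.peak_plv:>10.4f}{r.peak_freq:>12.2f}"
                f"{r.xcorr_max:>10.4f}{r.xcorr_lag * 1e3:>8.1f}"
            )
        lines.append("-" * 64)
        lines.append(
            f"{'hemisphere-collapsed':<24}{self.peak_plv:>10.4f}{self.peak_freq:>12.2f}"
            f"{self.xcorr_max:>10.4f}"
        )
        return "\n".join(lines)

    def plot_spectrum(self, ax=None):
        """PLV as a function of scan frequency, one line per source."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for spec in self.spectra:
            ax.plot(spec.center_freqs, spec.plv, label=spec.source_label)
        ax.axvline(self.model.train.spec.rate, ls=":", c="k", lw=0.8)
        ax.set_xlabel("center frequency (Hz)")
        ax.set_ylabel("PLV")
        ax.set_ylim(0, 1)
        ax.legend(frameon=False)
        ax.set_title(self.model.condition)
        return ax


class CohortTrendModel:
    """Group-level within-subject statistics for a cohort results table.

    Parameters
    ----------
    table : DataFrame
        Tidy table with ``subject_id, stimulus, rate, jitter`` and the value
        column (default ``peak_plv``); one row per subject x condition
        (collapse hemispheres first, e.g. via groupby().mean()).
    value : str
        Column to analyse.
    transform : {"sqrt", None}
        Variance-stabilising transform applied before testing.
    """

    def __init__(self, table: pd.DataFrame, value: str = "peak_plv", transform: str | None = "sqrt"):
        required = {"subject_id", "stimulus", "rate", "jitter", value}
        if not required.issubset(table.columns):
            raise InvalidParameterError(f"table must contain columns {sorted(required)}")
        self.table = table.copy()
        self.value = value
        self.transform = transform
        if transform == "sqrt":
            self.table[value] = stats.sqrt_transform(self.table[value])
        elif transform is not None:
            raise InvalidParameterError(f"unknown transform {transform!r}")

    def fit(self, jitter_rate: float = 4.5) -> "CohortTrendResults":
        tbl = self.table
        jitter_tbl = tbl[np.isclose(tbl["rate"], jitter_rate)]
        n_subjects = jitter_tbl["subject_id"].nunique()
        trends = {}
        for stim in sorted(jitter_tbl["stimulus"].unique()):
            sub = jitter_tbl[jitter_tbl["stimulus"] == stim]
            if sub["jitter"].nunique() >= 3 and n_subjects >= 3:
                trends[stim] = stats.linear_trend(sub, value=self.value, factor="jitter")
        contrasts = {}
        if jitter_tbl["stimulus"].nunique() == 2 and n_subjects >= 2:
            for j in sorted(jitter_tbl["jitter"].unique()):
                contrasts[j] = stats.paired_contrast(
                    jitter_tbl, between="stimulus", at={"jitter": j}, value=self.value
                )
        adjusted = stats.holm_adjust([c.p for c in contrasts.values()])
        adj_map = dict(zip(contrasts.keys(), adjusted))
        return CohortTrendResults(
            model=self, jitter_trends=trends, stimulus_contrasts=contrasts,
            holm_adjusted_p=adj_map,
        )


@dataclass
class CohortTrendResults:
    """Group statistics: jitter trends per stimulus and per-jitter contrasts."""

    model: CohortTrendModel
    jitter_trends: dict[str, stats.TrendResult]
    stimulus_contrasts: dict[float, stats.ContrastResult]
    holm_adjusted_p: dict[float, float]

    def summary(self) -> str:
        lines = [
            "Cohort trend fit",
            "=" * 72,
            f"value: {self.model.value} ({self.model.transform or 'no'} transform)",
            "-" * 72,
            "Within-subject linear trend across jitter",
            f"{'stimulus':<12}{'slope':>12}{'t':>10}{'df':>6}{'p':>12}",
        ]
        for stim, tr in self.jitter_trends.items():
            lines.append(f"{stim:<12}{tr.slope:>12.5f}{tr.t:>10.2f}{tr.df:>6d}{tr.p:>12.4g}")
        if self.stimulus_contrasts:
            lines += [
                "-" * 72,
                "Stimulus-domain paired contrasts per jitter (Holm-adjusted)",
                f"{'jitter':<12}{'mean diff':>12}{'t':>10}{'df':>6}{'p':>12}{'p_holm':>12}",
            ]
            for j, c in self.stimulus_contrasts.items():
                lines.append(
                    f"{j * 100:<12.0f}{c.mean_diff:>12.5f}{c.t:>10.2f}{c.df:>6d}"
                    f"{c.p:>12.4g}{self.holm_adjusted_p[j]:>12.4g}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "jitter_trends": {
                s: {"slope": t.slope, "t": t.t, "df": t.df, "p": t.p}
                for s, t in self.jitter_trends.items()
            },
            "stimulus_contrasts": {
                f"{j:g}": {
                    "mean_diff": c.mean_diff, "t": c.t, "df": c.df, "p": c.p,
                    "p_holm": self.holm_adjusted_p[j],
                }
                for j, c in self.stimulus_contrasts.items()
            },
        }
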