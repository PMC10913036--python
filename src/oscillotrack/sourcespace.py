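"""Scalp-to-source reduction via a linear source montage.

Multichannel EEG is reduced to left/right auditory-cortex (AC) source
waveforms by applying the (pseudo)inverse of a leadfield matrix L that maps
source currents (nAm) to scalp voltages (µV):  SWF = L⁻¹ × EEG.  Only the
tangential component of each hemisphere's AC source is carried, since that
orientation captures most of the variance of auditory cortical potentials.
For a non-square full-column-rank L the Moore--Penrose pseudoinverse is the
exact left inverse of the forward model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError


@dataclass(frozen=True)
class SourceMontage:
    """Leadfield matrix (channels x sources) with channel and source labels."""

    leadfield: np.ndarray
    channel_names: list[str]
    source_labels: list[str]

    def __post_init__(self) -> None:
        L = np.asarray(self.leadfield, dtype=float)
        object.__setattr__(self, "leadfield", L)
        if L.ndim != 2:
            raise InvalidParameterError("leadfield must be 2-D (channels x sources)")
        n_ch, n_src = L.shape
        if n_ch < n_src:
            raise InvalidParameterError(
                f"need at least as many channels ({n_ch}) as sources ({n_src})"
            )
        if len(self.channel_names) != n_ch:
            raise InvalidParameterError("channel_names length must match leadfield rows")
        if len(self.source_labels) != n_src:
            raise InvalidParameterError("source_labels length must match leadfield columns")

    @property
    def n_channels(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_sources(self) -> int:
        return self.leadfield.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "channel_names": self.channel_names,
            "source_labels": self.source_labels,
            "leadfield": self.leadfield.tolist(),  # row-major
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SourceMontage":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            leadfield=np.asarray(payload["leadfield"], dtype=float),
            channel_names=list(payload["channel_names"]),
            source_labels=list(payload["source_labels"]),
        )


@dataclass(frozen=True)
class SourceWaveforms:
    """Estimated source current time courses (sources x samples, nAm)."""

    currents: np.ndarray
    fs: float
    labels: list[str]

    @property
    def n_samples(self) -> int:
        return self.currents.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def rereference_common_average(eeg: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous channel mean from every channel."""
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2 or eeg.shape[0] < 2:
        raise InvalidParameterError("need a 2-D array with at least two channels")
    return eeg - eeg.mean(axis=0, keepdims=True)


def apply_montage(eeg: np.ndarray, montage: SourceMontage, fs: float) -> SourceWaveforms:
    """Project scalp EEG to source space: currents = pinv(L) @ EEG.

    ``eeg`` should be common-average referenced (a warning is issued if the
    channel means deviate noticeably from zero).
    """
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2:
        raise InvalidParameterError("eeg must be 2-D (channels x samples)")
    if eeg.shape[0] != montage.n_channels:
        raise InvalidParameterError(
            f"eeg has {eeg.shape[0]} channels but montage expects {montage.n_channels}"
        )
    L = montage.leadfield
    s = np.linalg.svd(L, compute_uv=False)
    if s[-1] <= s[0] * 1e-10:
        _, _, vt = np.linalg.svd(L)
        deficient = montage.source_labels[int(np.argmax(np.abs(vt[-1])))]
        raise InvalidParameterError(
            f"leadfield is rank deficient; source '{deficient}' is not separable"
        )
    scale = np.max(np.abs(eeg))
    if scale > 0:
        mean_dev = np.max(np.abs(eeg.mean(axis=0))) / scale
        if mean_dev > 1e-6:
            warnings.warn(
                "EEG does not appear to be common-average referenced "
                f"(relative channel-mean deviation {mean_dev:.2e})",
                stacklevel=2,
            )
    currents = np.linalg.pinv(L) @ eeg
    return SourceWaveforms(currents=currents, fs=float(fs), labels=list(montage.source_labels))


def extract_segment(sources: SourceWaveforms, start: float, length: float = 30.0) -> SourceWaveforms:
    """Extract an equal-length analysis segment ``[start, start + length)``."""
    if start < 0 or length <= 0:
        raise InvalidParameterError("start must be >= 0 and length positive")
    i0 = int(round(start * sources.fs))
    n = int(round(length * sources.fs))
    if i0 + n > sources.n_samples:
        raise InvalidParameterError(
            f"segment [{start}, {start + length}) s exceeds record of "
            f"{sources.duration:.2f} s"
        )
    return SourceWaveforms(
        currents=sources.currents[:, i0 : i0 + n],
        fs=sources.fs,
        labels=list(sources.labels),
    )


def match_channels(
    eeg: np.ndarray, eeg_names: list[str], montage: SourceMontage
) -> np.ndarray:
    """Reorder EEG rows to the montage's channel order (case-insensitive).

    Channels absent from the montage are dropped with a warning; channels
    required by the montage but missing from the recording raise an error.
    """
    lookup = {name.lower(): i for i, name in enumerate(eeg_names)}
    rows = []
    for name in montage.channel_names:
        i = lookup.get(name.lower())
        if i is None:
            raise InvalidParameterError(f"recording lacks montage channel '{name}'")
        rows.append(i)
    dropped = [n for n in eeg_names if n.lower() not in {c.lower() for c in montage.channel_names}]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} channels not in montage: {dropped[:5]}...", stacklevel=2)
    return np.asarray(eeg, dtype=float)[rows]
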