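"""File I/O: WAV stimulus audio, event sidecars, JSON manifests, EDF EEG.

WAV files are written as 32-bit float PCM via :mod:`scipy.io.wavfile`.
EDF files are written by a minimal built-in writer (classic EDF, 16-bit
integer samples, 1 s data records) and read through :mod:`mne`, which also
serves as the independent round-trip check in the test suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .exceptions import InvalidParameterError
from .stimgen import StimulusTrain

# --------------------------------------------------------------------------
# Stimulus train output
# --------------------------------------------------------------------------


def write_train(train: StimulusTrain, outdir, name: str) -> dict:
    """Write a train's WAV audio, TSV event sidecar, and JSON manifest.

    Returns the manifest dictionary.  Audio peak-normalized to 0.9 to avoid
    clipping in integer playback chains.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peak = np.max(np.abs(train.audio))
    audio = (train.audio / peak * 0.9 if peak > 0 else train.audio).astype(np.float32)
    wavfile.write(outdir / f"{name}.wav", int(round(train.fs)), audio)
    with open(outdir / f"{name}_events.tsv", "w") as fh:
        fh.write("onset_s\ttoken_kind\n")
        for on in train.onsets:
            fh.write(f"{on:.6f}\t{train.kind}\n")
    manifest = {
        "stimulus": train.kind,
        "rate_hz": train.spec.rate,
        "jitter_pct": round(train.spec.jitter * 100),
        "n_tokens": train.spec.n_tokens,
        "seed": train.spec.seed,
        "fs": train.fs,
    }
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# --------------------------------------------------------------------------
# EDF (classic, 16-bit)
# --------------------------------------------------------------------------


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path,
    data_uv: np.ndarray,
    fs: float,
    channel_names: list[str],
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> None:
    """Write channels x samples data (µV) to a classic EDF file.

    Uses 1 s data records, so ``fs`` must be a positive integer rate; the
    last record is zero-padded.  Each channel is scaled to the full 16-bit
    digital range from its own physical extremum.
    """
    data = np.atleast_2d(np.asarray(data_uv, dtype=float))
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise InvalidParameterError("channel_names must match data rows")
    spr = int(round(fs))
    if spr <= 0 or abs(spr - fs) > 1e-9:
        raise InvalidParameterError(f"EDF writer requires an integer sampling rate, got {fs}")
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    phys_max = np.maximum(np.max(np.abs(padded), axis=1), 1e-6)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768

    header = b""
    header += _pad("0", 8)
    header += _pad(patient_id, 80)
    header += _pad(recording_id, 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + n_ch)), 8)
    header += _pad("", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)  # record duration (s)
    header += _pad(str(n_ch), 4)
    header += b"".join(_pad(n, 16) for n in channel_names)
    header += b"".join(_pad("synthetic EEG", 80) for _ in range(n_ch))
    header += b"".join(_pad("uV", 8) for _ in range(n_ch))
    header += b"".join(_pad(f"{pm:.4f}"[:8], 8) for pm in phys_min)
    header += b"".join(_pad(f"{pm:.4f}"[:8], 8) for pm in phys_max)
    header += b"".join(_pad(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(_pad(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(_pad("", 80) for _ in range(n_ch))
    header += b"".join(_pad(str(spr), 8) for _ in range(n_ch))
    header += b"".join(_pad("", 32) for _ in range(n_ch))

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = padded[:, r * spr : (r + 1) * spr]
            dig = np.round((block - phys_min[:, None]) * gain[:, None] + dig_min)
            fh.write(dig.astype("<i2").tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (channels x samples in µV, fs, channel names)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


# --------------------------------------------------------------------------
# Cohort manifest
# --------------------------------------------------------------------------


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonify)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
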