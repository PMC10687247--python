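"""WAV and label-table input/output.

Canonical dialects: mono 16-bit PCM WAV at 44.1 kHz (other PCM formats
are accepted; multi-channel input is downmixed with a warning) and UTF-8
CSV label tables with header ``cycle_id,start_s,end_s,label`` where
times are seconds with 3-decimal precision over half-open
``[start, end)`` intervals and labels are exactly ``NS``/``VS``/``SS``.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .labels import validate_labels

__all__ = [
    "WavFormatError",
    "read_wav",
    "write_wav",
    "read_labels",
    "write_labels",
    "write_cycle_table",
]

LABEL_COLUMNS = ["cycle_id", "start_s", "end_s", "label"]


class WavFormatError(ValueError):
    """Raised when a WAV file cannot be read as PCM audio."""


_INT_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file as mono float samples in [-1, 1].

    Multi-channel audio is downmixed by channel averaging (with a
    warning).  Corrupt or non-PCM files raise :class:`WavFormatError`
    naming the file and its size in bytes.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as err:
        size = os.path.getsize(path) if path.exists() else "missing"
        raise WavFormatError(
            f"cannot read {path} as PCM WAV (file size {size} bytes): {err}"
        ) from err
    if data.ndim > 1:
        warnings.warn(
            f"{path}: {data.shape[1]}-channel audio downmixed to mono", stacklevel=2
        )
        data = data.mean(axis=1)
    if data.dtype in _INT_SCALE:
        samples = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise WavFormatError(f"{path}: unsupported WAV sample format {data.dtype}")
    return samples, int(rate)


def write_wav(path, samples: np.ndarray, sample_rate: int) -> None:
    """Write mono 16-bit PCM; samples are clipped to [-1, 1]."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(path, int(sample_rate), pcm)


def read_labels(path) -> pd.DataFrame:
    """Read a label table, validating header and label values."""
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: label table missing column(s) {missing}")
    validate_labels(df["label"].astype(str))
    if (df["end_s"] <= df["start_s"]).any():
        bad = df.index[df["end_s"] <= df["start_s"]].tolist()
        raise ValueError(f"{path}: end_s <= start_s at row(s) {bad}")
    return df[LABEL_COLUMNS]


def write_labels(path, table: pd.DataFrame) -> None:
    """Write a label table in the canonical dialect."""
    missing = [c for c in LABEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"label table missing column(s) {missing}")
    validate_labels(table["label"].astype(str))
    out = table[LABEL_COLUMNS].copy()
    out["start_s"] = out["start_s"].map(lambda v: f"{v:.3f}")
    out["end_s"] = out["end_s"].map(lambda v: f"{v:.3f}")
    out.to_csv(path, index=False)


def write_cycle_table(path, cycles, labels=None) -> None:
    """Write detected cycles as ``cycle_id,start_s,end_s`` (labels optional)."""
    df = pd.DataFrame(
        {
            "cycle_id": np.arange(len(cycles)),
            "start_s": [f"{c.start:.3f}" for c in cycles],
            "end_s": [f"{c.end:.3f}" for c in cycles],
        }
    )
    if labels is not None:
        df["label"] = list(labels)
    df.to_csv(path, index=False)
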