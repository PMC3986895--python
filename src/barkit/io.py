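"""File formats: mono PCM WAV, TSV element labels, CSV feature tables.

Declared dialects
-----------------
* WAV — mono, 16-bit PCM on write; any PCM/float mono WAV on read (stereo is
  rejected with instructions to convert). Arbitrary rates are accepted;
  analysis code resamples internally.
* Label TSV — header line ``onset_s\toffset_s\telement_type``, UTF-8, '.'
  decimal separator, times written to 0.1 ms.
* Feature CSV — comma separated, header row, identifier columns first, then
  feature columns; empty fields are missing values. LF line endings.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import ElementLabel, Waveform, validate_labels

__all__ = [
    "read_wav",
    "write_wav",
    "read_labels",
    "write_labels",
    "read_features",
    "write_features",
    "derive_seed",
]

LABEL_COLUMNS = ("onset_s", "offset_s", "element_type")


def read_wav(path: str | Path) -> Waveform:
    """Read a mono WAV file; integer PCM is rescaled to [-1, 1)."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono WAV, got {data.shape[1]} channels; "
            "convert to mono before analysis"
        )
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return Waveform(samples, int(rate))


def write_wav(path: str | Path, waveform: Waveform) -> None:
    """Write 16-bit PCM mono; samples are clipped to [-1, 1)."""
    clipped = np.clip(waveform.samples, -1.0, 32767 / 32768)
    wavfile.write(str(path), waveform.rate, np.round(clipped * 32768).astype(np.int16))


def write_labels(path: str | Path, labels: list[ElementLabel]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(LABEL_COLUMNS) + "\n")
        for lab in labels:
            fh.write(f"{lab.onset:.4f}\t{lab.offset:.4f}\t{lab.type}\n")


def _parse_time(token: str, path: str, lineno: int) -> float:
    if "," in token:
        raise ValueError(
            f"{path}:{lineno}: comma decimal separator in {token!r}; "
            "labels must use '.'"
        )
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed time field {token!r}") from None


def read_labels(path: str | Path) -> list[ElementLabel]:
    labels: list[ElementLabel] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != LABEL_COLUMNS:
            raise ValueError(
                f"{path}:1: expected header {LABEL_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            onset = _parse_time(fields[0], str(path), lineno)
            offset = _parse_time(fields[1], str(path), lineno)
            labels.append(ElementLabel(onset, offset, fields[2]))
    validate_labels(labels)
    return labels


def write_features(path_or_buf, table: pd.DataFrame) -> None:
    """Write a feature table as CSV (missing values as empty fields)."""
    table.to_csv(path_or_buf, index=False, lineterminator="\n")


def read_features(path: str | Path | _io.TextIOBase) -> pd.DataFrame:
    """Read a feature CSV; empty fields become NaN, rows are retained."""
    return pd.read_csv(path)


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from one global seed.

    Every stochastic stage draws its own named substream so that a single
    ``--seed`` reproduces the whole pipeline.
    """
    digest = np.frombuffer(stage.encode("utf-8"), dtype=np.uint8)
    entropy = [int(master_seed) & 0x7FFFFFFF, *(int(b) for b in digest)]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % (2**31))
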