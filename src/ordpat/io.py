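"""Readers and writers for single-channel series.

Supported inputs: one-value-per-row text/CSV (first column used, header
auto-detected, configurable missing-value sentinels) and RIFF WAV PCM
audio (mono or first channel; amplitudes are used raw, since order
patterns are invariant under monotone rescaling).  Output series are
single-column CSV with ``NaN`` for missing entries, so a write/read
round trip is lossless.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .series import TimeSeries

__all__ = ["read_series", "write_series", "DEFAULT_SENTINELS"]

DEFAULT_SENTINELS: tuple[str, ...] = ("", "NA", "NaN", "nan", "NAN", "null")

_TEXT_EXT = {".csv", ".txt", ".tsv", ".dat"}


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext == ".wav":
        return "wav"
    if ext in _TEXT_EXT:
        return "csv"
    raise ValueError(
        f"cannot infer format from {path.name!r}; pass format='csv' or 'wav'"
    )


def _read_text(path: Path, sentinels: tuple[str, ...]) -> TimeSeries:
    try:
        df = pd.read_csv(
            path,
            header=None,
            comment="#",
            na_values=list(sentinels),
            keep_default_na=True,
            skip_blank_lines=True,
            skipinitialspace=True,
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file contains no data rows") from None
    col = df.iloc[:, 0]
    # header auto-detection: a non-numeric, non-sentinel first row is a header
    if col.dtype == object:
        first = str(col.iloc[0]).strip()
        try:
            float(first)
        except ValueError:
            col = col.iloc[1:]
        col = pd.to_numeric(col, errors="raise")
    values = col.to_numpy(dtype=np.float64)
    if values.size == 0:
        raise ValueError(f"{path}: no numeric rows")
    return TimeSeries(values)


def _read_wav(path: Path) -> TimeSeries:
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        data = data[:, 0]
    if data.size == 0:
        raise ValueError(f"{path}: empty audio stream")
    return TimeSeries(data.astype(np.float64), sample_rate=float(rate))


def read_series(
    path: str | os.PathLike,
    format: str | None = None,
    sentinels: tuple[str, ...] = DEFAULT_SENTINELS,
) -> TimeSeries:
    """Read a series from CSV/TXT (first column) or WAV (first channel).

    Parameters
    ----------
    path
        Input file.
    format
        ``"csv"``, ``"txt"`` or ``"wav"``; inferred from the extension
        when omitted.
    sentinels
        Strings mapped to missing values in text input.

    Raises
    ------
    ValueError
        Unknown format, empty file, or no numeric rows.
    FileNotFoundError
        Missing input file.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    fmt = format or _detect_format(p)
    if fmt in ("csv", "txt"):
        return _read_text(p, tuple(sentinels))
    if fmt == "wav":
        return _read_wav(p)
    raise ValueError(f"unsupported format {fmt!r}; expected csv, txt or wav")


def write_series(path: str | os.PathLike, series: TimeSeries) -> None:
    """Write a series as single-column CSV, ``NaN`` for missing entries."""
    with open(path, "w") as fh:
        for v in series.values:
            fh.write("NaN\n" if np.isnan(v) else f"{float(v)!r}\n")
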