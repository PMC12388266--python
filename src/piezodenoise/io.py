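"""Signal file I/O: WAV (PCM16 or IEEE float32) and CSV.

CSV files are comma-delimited with '.' decimals, one or two numeric
columns, and an optional single header line; the sampling rate comes from
the configuration.  PCM16 WAV samples are scaled to [-1, 1) by 1/32768 on
read and symmetrically on write; float WAVs pass through unscaled.
"""

from __future__ import annotations

import csv
import os

import numpy as np
from scipy.io import wavfile

from .signal_prep import TimeSeries

__all__ = ["read_signal", "write_signal"]


def _infer_format(path, fmt: str | None) -> str:
    if fmt:
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".wav", ".wave"):
        return "wav"
    if ext in (".csv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer format of {path!r}; pass format=")


def read_signal(path, fmt: str | None = None, rate: float = 8000.0
                ) -> list[TimeSeries]:
    """Read one or two channels from a WAV or CSV file.

    Returns a list with one TimeSeries per channel (two-channel files feed
    the linear-superposition fusion step).
    """
    fmt = _infer_format(path, fmt)
    if fmt == "wav":
        try:
            file_rate, data = wavfile.read(path)
        except Exception as exc:
            raise ValueError(f"cannot parse WAV file {path!r}: {exc}") from exc
        if data.size == 0:
            raise ValueError(f"WAV file {path!r} contains no samples")
        if data.dtype == np.int16:
            data = data.astype(float) / 32768.0
        elif data.dtype == np.int32:
            data = data.astype(float) / 2147483648.0
        else:
            data = data.astype(float)
        data = data[:, None] if data.ndim == 1 else data
        return [TimeSeries(samples=data[:, c], rate=float(file_rate))
                for c in range(data.shape[1])]

    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for ln, row in enumerate(reader, start=1):
            row = [cell for cell in row if cell.strip()]
            if not row:
                continue
            try:
                rows.append([float(c) for c in row])
            except ValueError as exc:
                if ln == 1 and not rows:
                    continue          # single optional header line
                raise ValueError(
                    f"cannot parse {path!r} line {ln}: {exc}") from exc
    if not rows:
        raise ValueError(f"no numeric data found in {path!r}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(
            f"ragged CSV {path!r}: row widths {sorted(widths)} differ")
    n_cols = widths.pop()
    if n_cols not in (1, 2):
        raise ValueError(
            f"{path!r} has {n_cols} columns; expected one or two channels")
    arr = np.asarray(rows, dtype=float)
    return [TimeSeries(samples=arr[:, c], rate=rate)
            for c in range(n_cols)]


def write_signal(path, signals: TimeSeries | list[TimeSeries],
                 fmt: str | None = None, pcm16: bool = False) -> None:
    """Write one or two channels to WAV (float32, or PCM16 on request) or
    CSV."""
    if isinstance(signals, TimeSeries):
        signals = [signals]
    if not 1 <= len(signals) <= 2:
        raise ValueError("write_signal handles one or two channels")
    if len({len(s) for s in signals}) != 1:
        raise ValueError("channels must have equal length")
    fmt = _infer_format(path, fmt)
    data = np.column_stack([s.samples for s in signals])
    if fmt == "wav":
        rate = int(round(signals[0].rate))
        out = data[:, 0] if data.shape[1] == 1 else data
        if pcm16:
            wavfile.write(path, rate,
                          np.clip(np.round(out * 32768.0),
                                  -32768, 32767).astype(np.int16))
        else:
            wavfile.write(path, rate, out.astype(np.float32))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in data:
            writer.writerow([f"{v:.10g}" for v in row])
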