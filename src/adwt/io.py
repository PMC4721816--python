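"""Delimited-text readers and writers shared by the CLI and the library.

One dialect everywhere: comma-separated, "." decimal, header row, UTF-8,
LF, scientific notation permitted.  Artifact files embed their generating
configuration as ``# adwt-config: {json}`` comment lines so a run can be
reproduced from any output file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import Signal

__all__ = ["read_signal", "write_signal", "write_table", "read_config_header"]

_CONFIG_PREFIX = "# adwt-config: "


def _config_lines(config: dict | None) -> str:
    if not config:
        return ""
    return _CONFIG_PREFIX + json.dumps(config, sort_keys=True) + "\n"


def read_config_header(path) -> dict:
    """Parse the embedded configuration of an artifact file ({} if none)."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith(_CONFIG_PREFIX):
                return json.loads(line[len(_CONFIG_PREFIX):])
            if not line.startswith("#"):
                break
    return {}


def read_signal(path, fs_override: float | None = None) -> Signal:
    """Read a sampled signal from delimited text.

    Accepts either a ``time_s`` first column plus one or more value
    columns, or value columns only with ``fs_override`` supplied.  The time
    column must be uniform within 1e-6 relative.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ValueError(f"{path}: non-numeric columns")
    first = df.columns[0].lower()
    has_time = first in ("time_s", "time", "t") or (
        df.shape[1] >= 2 and fs_override is None
    )
    if has_time and df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2:
            raise ValueError(f"{path}: need at least 2 samples to infer fs")
        if np.max(np.abs(dt - dt.mean())) > 1e-6 * abs(dt.mean()):
            if fs_override is None:
                raise ValueError(f"{path}: non-uniform time column and no fs given")
            fs = fs_override
        else:
            fs = 1.0 / dt.mean()
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        t0 = float(t[0])
    else:
        if fs_override is None:
            raise ValueError(f"{path}: value-only file requires a sampling rate")
        fs = fs_override
        values = df.to_numpy(dtype=float)
        t0 = 0.0
    if values.shape[1] == 1:
        values = values[:, 0]
    return Signal(values, float(fs), t0)


def write_signal(path, signal: Signal, config: dict | None = None) -> None:
    """Write a signal as ``time_s`` plus one column per channel."""
    path = Path(path)
    vals = signal.values if signal.values.ndim == 2 else signal.values[:, None]
    cols = {"time_s": signal.times}
    for c in range(vals.shape[1]):
        cols[f"ch{c + 1}" if vals.shape[1] > 1 else "value"] = vals[:, c]
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_config_lines(config))
        df.to_csv(fh, index=False, lineterminator="\n")


def write_table(path, df: pd.DataFrame, config: dict | None = None) -> None:
    """Write any tabular artifact with an embedded configuration header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_config_lines(config))
        df.to_csv(fh, index=False, lineterminator="\n")
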