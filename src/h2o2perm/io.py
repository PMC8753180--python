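"""Reading and writing the package's delimited-text formats.

Dialect: comma-separated, '.' decimal, UTF-8, header mandatory.  Time courses
are two-column CSVs (``t_s``, ``signal``); a series is described by a manifest
CSV (``trace_file``, ``amount``, ``amount_units``, ``temperature_C``,
``signal_kind``, ``pathlength_cm``).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin
from .latency import SignalKind, TimeCourse


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


def read_timecourse_csv(
    path: str | Path,
    signal_kind: SignalKind | str = SignalKind.concentration,
    amount: float = math.nan,
    temperature: float = math.nan,
    pathlength: float = 1.0,
) -> TimeCourse:
    """Read a two-column (time, signal) CSV into a validated TimeCourse."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (t_s, signal)")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    y = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = t.isna() | y.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: non-numeric value at line {line}")
    t = t.to_numpy(float)
    if not np.all(np.diff(t) > 0):
        i = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 3
        raise ParseError(f"{path}: time not strictly increasing at line {i}")
    return TimeCourse(
        t=t, y=y.to_numpy(float), signal_kind=SignalKind(signal_kind),
        amount=amount, temperature=temperature, pathlength=pathlength,
        label=path.stem,
    )


def write_timecourse_csv(tc: TimeCourse, path: str | Path) -> None:
    pd.DataFrame({"t_s": tc.t, "signal": tc.y}).to_csv(
        Path(path), index=False, float_format="%.10g"
    )


MANIFEST_COLUMNS = (
    "trace_file", "amount", "amount_units", "temperature_C", "signal_kind",
    "pathlength_cm",
)


def read_manifest(path: str | Path) -> list[TimeCourse]:
    """Read a manifest CSV and load every trace it references.

    Trace paths are resolved relative to the manifest's directory; a missing
    trace file raises ``FileNotFoundError`` naming the file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: manifest missing columns {missing_cols}")
    traces = []
    for _, row in df.iterrows():
        trace_path = path.parent / str(row["trace_file"])
        if not trace_path.exists():
            raise FileNotFoundError(f"manifest references missing trace file: {trace_path}")
        traces.append(
            read_timecourse_csv(
                trace_path,
                signal_kind=row["signal_kind"],
                amount=float(row["amount"]),
                temperature=celsius_to_kelvin(float(row["temperature_C"])),
                pathlength=float(row["pathlength_cm"]),
            )
        )
    return traces
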