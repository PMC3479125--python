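"""Trace and event-table file formats.

The canonical trace format is CSV with ``# key=value`` metadata header
lines followed by a column-name row and three columns (time_s, current_pA,
voltage_mV, in any order).  Values are serialized at full precision so a
write/read round trip is bit-exact.  There is no public file dialect for
painted-bilayer rigs, so this plain-text format is the interchange format
of the pipeline; converters from vendor formats are adapters on top of it.
"""

from __future__ import annotations

import io
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .gating_model import CurrentTrace
from .idealization import Idealization, Segment, SegmentationParams

TRACE_COLUMNS = ("time_s", "current_pA", "voltage_mV")
EVENT_COLUMNS = ("trace", "start_s", "end_s", "duration_s", "voltage_mV",
                 "mean_current_pA", "conductance_nS", "state")


class TraceFormatError(ValueError):
    pass


def _parse_meta_value(text: str):
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            continue
    return text


def read_trace(path) -> CurrentTrace:
    """Read a trace CSV, validating metadata, columns and time base."""
    path = Path(path)
    meta: dict = {}
    body_lines: list[str] = []
    body_start = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("#"):
                kv = stripped.lstrip("#").strip()
                if "=" not in kv:
                    raise TraceFormatError(
                        f"{path}:{lineno}: malformed header line {stripped!r}")
                key, value = kv.split("=", 1)
                meta[key.strip()] = _parse_meta_value(value.strip())
            elif stripped:
                if not body_lines:
                    body_start = lineno
                body_lines.append(line)
    if "fs_hz" not in meta:
        raise TraceFormatError(f"{path}: missing required header key 'fs_hz'")
    fs = float(meta["fs_hz"])

    try:
        df = pd.read_csv(io.StringIO("".join(body_lines)))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TraceFormatError(f"{path}: body parse failed: {exc}") from exc
    if set(df.columns) != set(TRACE_COLUMNS) or len(df.columns) != 3:
        raise TraceFormatError(
            f"{path}:{body_start}: expected columns {TRACE_COLUMNS} "
            f"(any order), got {tuple(df.columns)}")
    for col in TRACE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(vals.index[vals.isna()][0])
            raise TraceFormatError(
                f"{path}:{body_start + 1 + bad}: non-numeric value in column {col!r}")
        df[col] = vals

    t = df["time_s"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        if (dt <= 0).any() or not np.allclose(dt, 1.0 / fs, rtol=0, atol=1e-9 / fs + 1e-12):
            bad = int(np.argmax(~np.isclose(dt, 1.0 / fs, rtol=0, atol=1e-9 / fs + 1e-12)))
            raise TraceFormatError(
                f"{path}:{body_start + 2 + bad}: time not strictly increasing "
                f"at 1/fs_hz spacing")
    meta_out = {k: v for k, v in meta.items() if k != "fs_hz"}
    return CurrentTrace(fs_Hz=fs, current_pA=df["current_pA"].to_numpy(),
                        voltage_mV=df["voltage_mV"].to_numpy(), meta=meta_out)


def write_trace(trace: CurrentTrace, path) -> None:
    """Write a trace CSV with full-precision values (round-trip safe)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={trace.fs_Hz!r}\n")
        for key, value in trace.meta.items():
            fh.write(f"# {key}={value}\n")
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        t = trace.time_s
        for i in range(trace.n_samples):
            fh.write(f"{float(t[i])!r},{float(trace.current_pA[i])!r},"
                     f"{float(trace.voltage_mV[i])!r}\n")


def events_to_dataframe(idealizations: list[Idealization]) -> pd.DataFrame:
    rows = []
    for ti, ideal in enumerate(idealizations):
        for s in ideal.segments:
            rows.append((ti, s.start_s, s.end_s, s.duration_s, s.voltage_mV,
                         s.mean_current_pA, s.conductance_nS, s.state))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def dataframe_to_idealizations(df: pd.DataFrame,
                               baseline_pA: float = 0.0) -> list[Idealization]:
    """Rebuild per-trace idealizations from an event table."""
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise TraceFormatError(f"event table missing columns: {sorted(missing)}")
    out = []
    for _, group in df.groupby("trace", sort=True):
        segs = [Segment(start_s=r.start_s, end_s=r.end_s,
                        mean_current_pA=r.mean_current_pA, voltage_mV=r.voltage_mV,
                        conductance_nS=r.conductance_nS, state=r.state)
                for r in group.sort_values("start_s").itertuples()]
        out.append(Idealization(segments=segs, baseline_pA=baseline_pA,
                                params=SegmentationParams()))
    return out


def write_events(idealizations: list[Idealization], path) -> None:
    events_to_dataframe(idealizations).to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)
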