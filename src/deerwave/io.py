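"""Delimited-text readers and writers.

All formats are plain UTF-8 text with '.' decimal separators, LF line
endings and a single header line; readers tolerate comment lines starting
with '#'.  Column orders are fixed:

* traces    — ``t_us, V``
* waveforms — ``time_ns, amplitude, freq_MHz, phase_rad, I, Q``
* profiles  — ``offset_MHz, Mz, inversion_efficiency``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .deer_model import DeerTrace
from .spin_dynamics import InversionProfile
from .waveforms import Waveform, quadrature_components

__all__ = [
    "read_trace",
    "write_trace",
    "write_waveform",
    "write_profile",
    "TraceParseError",
]


class TraceParseError(ValueError):
    """A trace file violated the format contract; carries the offending line."""


def read_trace(path: Path | str) -> DeerTrace:
    """Read a two-column (time, signal) trace.

    Time units are auto-detected: values above 100 are interpreted as ns and
    converted to µs.  Non-monotone time columns and NaN values raise
    :class:`TraceParseError` naming the first offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise TraceParseError(f"{path}: expected two numeric columns")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    nan_rows = np.flatnonzero(np.isnan(t) | np.isnan(v))
    if nan_rows.size:
        raise TraceParseError(f"{path}: NaN value at data line {nan_rows[0] + 1}")
    if np.max(np.abs(t)) > 100:  # ns-scale axis
        t = t / 1e3
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise TraceParseError(
            f"{path}: time column not strictly increasing at data line {bad[0] + 2}"
        )
    return DeerTrace(t, v)


def write_trace(trace: DeerTrace, path: Path | str) -> None:
    """Write ``t_us, V`` with full float round-trip precision."""
    df = pd.DataFrame({"t_us": trace.t_grid, "V": trace.v})
    df.to_csv(Path(path), index=False, lineterminator="\n", float_format="%.17g")


def write_waveform(w: Waveform, path: Path | str) -> None:
    i, q = quadrature_components(w)
    df = pd.DataFrame(
        {
            "time_ns": w.time_grid * 1e9,
            "amplitude": w.amplitude,
            "freq_MHz": w.frequency / 1e6,
            "phase_rad": w.phase,
            "I": i,
            "Q": q,
        }
    )
    df.to_csv(Path(path), index=False, lineterminator="\n", float_format="%.17g")


def write_profile(profile: InversionProfile, path: Path | str) -> None:
    df = pd.DataFrame(
        {
            "offset_MHz": profile.offsets / 1e6,
            "Mz": profile.mz,
            "inversion_efficiency": profile.efficiency,
        }
    )
    df.to_csv(Path(path), index=False, lineterminator="\n", float_format="%.17g")
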