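"""Uniformly sampled intracellular voltage traces and their CSV on-disk form.

A :class:`VoltageTrace` is the common currency of the package: every
generator, preprocessing step and analysis consumes and returns one.  Time is
in seconds, membrane potential in millivolts.  Traces are stored as a start
time, a sampling rate and a dense value array; the explicit time axis is
derived, which guarantees uniform sampling by construction.

On disk a trace is a two-column delimited text file with header
``time_s,voltage_mV``.  The reader validates that the time column is uniform
(relative tolerance 1e-6) and that all voltages are finite, reporting the
offending line number otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class TraceFormatError(ValueError):
    """Raised when an on-disk trace violates the CSV contract."""


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane-potential series with free-form metadata.

    Parameters
    ----------
    start_time:
        Time of the first sample, in seconds.
    sample_rate:
        Sampling rate in Hz; must be positive.
    values:
        Membrane potential samples in mV; at least two finite values.
    metadata:
        Free-form annotations (cell id, condition, processing flags ...).
    """

    start_time: float
    sample_rate: float
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a voltage trace needs at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voltage trace contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def with_values(self, values: np.ndarray, **metadata_updates) -> "VoltageTrace":
        """Copy of this trace with new samples (same time base)."""
        md = dict(self.metadata)
        md.update(metadata_updates)
        return VoltageTrace(self.start_time, self.sample_rate, np.asarray(values, float), md)

    def copy(self) -> "VoltageTrace":
        return dataclasses.replace(self, values=self.values.copy(),
                                   metadata=dict(self.metadata))


def write_trace_csv(trace: VoltageTrace, path, delimiter: str = ",") -> None:
    """Write a trace as delimited text with header ``time_s,voltage_mV``.

    Values are printed with 17 significant digits so that a write/read round
    trip reproduces the trace to well below 1e-9 mV.
    """
    times = trace.times
    with open(path, "w") as fh:
        fh.write(f"time_s{delimiter}voltage_mV\n")
        for t, v in zip(times, trace.values):
            fh.write(f"{t:.17g}{delimiter}{v:.17g}\n")


def read_trace_csv(path, delimiter: str = ",",
                   metadata: Optional[dict] = None) -> VoltageTrace:
    """Read a delimited trace file, validating header, uniformity, finiteness.

    Raises
    ------
    TraceFormatError
        On a malformed header, non-finite voltages, or a time column that is
        not uniform to a relative tolerance of 1e-6 (the message names the
        first offending data line).
    """
    df = pd.read_csv(path, sep=delimiter)
    cols = [c.strip() for c in df.columns]
    if cols[:2] != ["time_s", "voltage_mV"]:
        raise TraceFormatError(
            f"{path}: expected header 'time_s{delimiter}voltage_mV', got {list(df.columns)!r}")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise TraceFormatError(f"{path}: need at least two samples")
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise TraceFormatError(f"{path}: non-finite voltage at data line {bad + 2}")
    if not np.all(np.isfinite(t)):
        bad = int(np.flatnonzero(~np.isfinite(t))[0])
        raise TraceFormatError(f"{path}: non-finite time at data line {bad + 2}")
    steps = np.diff(t)
    dt = np.median(steps)
    if dt <= 0:
        raise TraceFormatError(f"{path}: time column not increasing")
    rel = np.abs(steps - dt) / dt
    if np.any(rel > 1e-6):
        bad = int(np.argmax(rel > 1e-6))
        raise TraceFormatError(
            f"{path}: non-uniform sampling at data line {bad + 3} "
            f"(step {steps[bad]:g} s vs expected {dt:g} s)")
    return VoltageTrace(start_time=float(t[0]), sample_rate=1.0 / float(dt),
                        values=v, metadata=dict(metadata or {}))
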