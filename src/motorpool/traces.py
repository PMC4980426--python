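"""Uniformly sampled time-series traces and their CSV dialect.

A trace is the common currency of the spectral analysis: a muscle-length
waveform or a fluorescence (ΔF/F) signal sampled at a fixed rate. The CSV
dialect used throughout the package has a ``time_s`` column followed by one
column per trace; sampling uniformity is validated on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesTrace",
    "InsufficientDataError",
    "read_traces_csv",
    "write_traces_csv",
]


class InsufficientDataError(ValueError):
    """Raised when a trace is too short for the requested analysis."""


@dataclass
class TimeSeriesTrace:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    label
        Name of the signal (e.g. ``"LO1_A4"``).
    sampling_rate
        Samples per second, strictly positive.
    values
        The samples; at least two, all finite (gaps must be rejected or
        filled upstream).
    start_time
        Time of the first sample in seconds.
    """

    label: str
    sampling_rate: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise InsufficientDataError(
                f"trace {self.label!r} needs >= 2 samples, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trace {self.label!r} contains non-finite samples")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sampling_rate

    def demeaned(self) -> np.ndarray:
        """Samples with the mean removed (used before tapering)."""
        return self.values - self.values.mean()


def _validate_uniform(time_s: np.ndarray, path: str, tol: float = 0.01) -> float:
    """Check uniform sampling; return the sampling rate.

    The maximum deviation of any inter-sample interval from the mean interval
    must be below ``tol`` (fraction of the mean interval).
    """
    dt = np.diff(time_s)
    if dt.size == 0:
        raise InsufficientDataError(f"{path}: fewer than 2 rows")
    mean_dt = float(dt.mean())
    if mean_dt <= 0:
        raise ValueError(f"{path}: time_s column must be strictly increasing")
    if np.max(np.abs(dt - mean_dt)) > tol * mean_dt:
        raise ValueError(
            f"{path}: non-uniform sampling (max interval deviation exceeds "
            f"{tol:.0%} of the mean interval {mean_dt:.6g} s)"
        )
    return 1.0 / mean_dt


def read_traces_csv(path: str) -> dict[str, TimeSeriesTrace]:
    """Read the trace CSV dialect: ``time_s`` plus one column per signal."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    df = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    if df.isna().any().any():
        bad = df.isna().any(axis=1)
        row = int(np.where(bad)[0][0]) + 2  # 1-based + header line
        raise ValueError(f"{path}: missing or non-numeric value at line {row}")
    time_s = df["time_s"].to_numpy(dtype=float)
    fs = _validate_uniform(time_s, path)
    traces = {}
    for col in df.columns:
        if col == "time_s":
            continue
        traces[col] = TimeSeriesTrace(
            label=col,
            sampling_rate=fs,
            values=df[col].to_numpy(dtype=float),
            start_time=float(time_s[0]),
        )
    if not traces:
        raise ValueError(f"{path}: no trace columns besides time_s")
    return traces


def write_traces_csv(path: str, traces: dict[str, TimeSeriesTrace] | list[TimeSeriesTrace]) -> None:
    """Write traces sharing one clock to the CSV dialect."""
    if isinstance(traces, dict):
        traces = list(traces.values())
    if not traces:
        raise ValueError("no traces to write")
    n = len(traces[0])
    fs = traces[0].sampling_rate
    t0 = traces[0].start_time
    for tr in traces[1:]:
        if len(tr) != n or tr.sampling_rate != fs or tr.start_time != t0:
            raise ValueError("all traces in one file must share length, rate and start")
    data = {"time_s": t0 + np.arange(n) / fs}
    for tr in traces:
        data[tr.label] = tr.values
    pd.DataFrame(data).to_csv(path, index=False)
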