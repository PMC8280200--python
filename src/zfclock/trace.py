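"""Time-series container and plate CSV input/output.

A :class:`Trace` is one luminescence recording: times in hours, values in
arbitrary units, with optional well/treatment metadata.  Plates are stored
as wide CSV (column 1 ``time_h``, one column per well) with a companion
metadata table (well, treatment, concentration) when treatments matter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["Trace", "TraceStats", "GroupStats", "read_plate", "write_plate"]


@dataclass
class Trace:
    times: np.ndarray
    values: np.ndarray
    well: str | None = None
    treatment: str | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def stats(self) -> "TraceStats":
        return TraceStats(float(np.mean(self.values)), float(np.std(self.values, ddof=1)))

    def with_values(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float))

    def window(self, start_h: float, end_h: float) -> "Trace":
        """Restrict to times in [start_h, end_h)."""
        m = (self.times >= start_h) & (self.times < end_h)
        return replace(self, times=self.times[m], values=self.values[m])


@dataclass(frozen=True)
class TraceStats:
    """Sample mean and standard deviation (n-1 denominator) of one trace."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def is_constant(self) -> bool:
        return self.sd == 0.0


@dataclass(frozen=True)
class GroupStats:
    """Mean of per-trace means and mean of per-trace SDs over a treatment group."""

    mean_of_means: float
    mean_of_sds: float
    n_traces: int

    def __post_init__(self) -> None:
        if self.n_traces < 1:
            raise ValueError("group aggregates need at least one trace")

    @classmethod
    def from_traces(cls, traces: list[Trace]) -> "GroupStats":
        stats = [t.stats for t in traces]
        return cls(
            float(np.mean([s.mean for s in stats])),
            float(np.mean([s.sd for s in stats])),
            len(traces),
        )


def read_plate(path, meta_path=None) -> list[Trace]:
    """Read a wide plate CSV (time_h + one column per well) into traces."""
    df = pd.read_csv(path)
    if df.columns[0] != "time_h":
        raise ValueError(f"{path}: first column must be 'time_h', got {df.columns[0]!r}")
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path).set_index("well")
    traces = []
    t = df["time_h"].to_numpy()
    for col in df.columns[1:]:
        kw = {}
        if meta is not None and col in meta.index:
            row = meta.loc[col]
            kw = {"treatment": row.get("treatment"), "concentration": row.get("concentration")}
        traces.append(Trace(t, df[col].to_numpy(), well=col, **kw))
    return traces


def write_plate(traces: list[Trace], path) -> None:
    times = traces[0].times
    for t in traces[1:]:
        if not np.array_equal(t.times, times):
            raise ValueError("all traces must share one time grid")
    data = {"time_h": times}
    for k, t in enumerate(traces):
        data[t.well or f"w{k:02d}"] = t.values
    pd.DataFrame(data).to_csv(path, index=False)
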