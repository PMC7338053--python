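"""Per-structure fluorescence time series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Trace", "traces_to_frame", "traces_from_frame"]


@dataclass
class Trace:
    """A fluorescence time series for one structure and one channel role.

    Attributes
    ----------
    structure : str
        Persistent structure identifier (e.g. a track id).
    role : str
        Channel role that was measured inside the structure's mask.
    times : ndarray
        Sample times in seconds, strictly increasing.
    values : ndarray
        Background-subtracted fluorescence in arbitrary units, floored at 0.
    klass : str
        Marker role (compartment class) that defined the mask.
    """

    structure: str
    role: str
    times: np.ndarray
    values: np.ndarray
    klass: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        if len(self) < 2:
            raise ValueError("trace has fewer than 2 samples")
        return float(np.median(np.diff(self.times)))

    def with_values(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float))

    def shifted(self, dt: float) -> "Trace":
        return replace(self, times=self.times + dt)


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Tidy long-format table: structure, class, role, time_s, value."""
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "structure": tr.structure,
            "class": tr.klass,
            "role": tr.role,
            "time_s": tr.times,
            "value": tr.values,
        }))
    if not rows:
        return pd.DataFrame(
            columns=["structure", "class", "role", "time_s", "value"])
    return pd.concat(rows, ignore_index=True)


def traces_from_frame(df: pd.DataFrame) -> list[Trace]:
    """Inverse of :func:`traces_to_frame` (one trace per structure/role)."""
    out = []
    for (structure, role), grp in df.groupby(["structure", "role"],
                                             sort=True):
        grp = grp.sort_values("time_s")
        klass = str(grp["class"].iloc[0]) if "class" in grp else ""
        out.append(Trace(structure=str(structure), role=str(role),
                         times=grp["time_s"].to_numpy(),
                         values=grp["value"].to_numpy(), klass=klass))
    return out
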