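"""Normalization, alignment and averaging of Golgi maturation traces.

A maturation event is one cisterna followed through the early-to-late
transition: the early marker (Vrg4-like) decays while the late marker
(Sec7-like) rises.  Traces are normalized either to the mean of their three
highest values (robust peak normalization for markers) or to the mean of
their first/last six values (for cargo and markers whose plateau anchors
the event window); events are aligned at the early/late crossing time and
averaged on a common 2 s grid with SEM bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import Trace

__all__ = [
    "MaturationEvent",
    "AlignedAverage",
    "MaturationError",
    "normalize_top3",
    "normalize_endpoint6",
    "transition_midpoint",
    "align_and_average",
    "adaptor_timing",
]


class MaturationError(ValueError):
    """The traces do not describe a usable maturation event."""


@dataclass
class MaturationEvent:
    """One cisterna's traces plus its (estimated or true) midpoint."""

    cisterna: str
    traces: dict[str, Trace]
    midpoint: float


@dataclass
class AlignedAverage:
    """Midpoint-aligned population average of maturation events."""

    rel_times: np.ndarray
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    n_events: int
    counts: dict[str, np.ndarray]

    def value_at(self, role: str, rel_time: float) -> float:
        """Mean value at the grid point nearest ``rel_time``."""
        idx = int(np.argmin(np.abs(self.rel_times - rel_time)))
        return float(self.mean[role][idx])


def normalize_top3(trace: Trace) -> Trace:
    """Normalize a trace to the average of its three highest values."""
    if len(trace) < 3:
        raise MaturationError("trace shorter than 3 samples")
    top3 = np.sort(trace.values)[-3:].mean()
    if top3 <= 0:
        raise MaturationError("all-zero trace cannot be normalized")
    return trace.with_values(trace.values / top3)


def normalize_endpoint6(trace: Trace, anchor: str = "head") -> Trace:
    """Normalize to the mean of the first six (head) or last six (tail)
    values — the convention for cargo/early-marker (head) and late-marker
    (tail) traces over an event window."""
    if len(trace) < 6:
        raise MaturationError("trace shorter than 6 samples")
    if anchor == "head":
        ref = trace.values[:6].mean()
    elif anchor == "tail":
        ref = trace.values[-6:].mean()
    else:
        raise ValueError("anchor must be 'head' or 'tail'")
    if ref <= 0:
        raise MaturationError("anchor-window mean is not positive")
    return trace.with_values(trace.values / ref)


def transition_midpoint(early: Trace, late: Trace) -> float:
    """Crossing time of the normalized early and late marker traces.

    The midpoint is the time at which the late trace first rises above the
    early trace, linearly interpolated between the bracketing frames.  If
    several crossings exist, the one nearest the late trace's half-maximum
    time is used.  Both traces must share a time base (peak-normalized).
    """
    t0 = max(early.times[0], late.times[0])
    t1 = min(early.times[-1], late.times[-1])
    if t1 <= t0:
        raise MaturationError("traces do not overlap in time")
    # restrict to the common span on the early trace's grid
    sel = (early.times >= t0) & (early.times <= t1)
    t = early.times[sel]
    e = early.values[sel]
    lv = np.interp(t, late.times, late.values)
    diff = lv - e
    crossings = []
    for i in range(1, t.size):
        if diff[i - 1] < 0 <= diff[i]:
            frac = -diff[i - 1] / (diff[i] - diff[i - 1])
            crossings.append(t[i - 1] + frac * (t[i] - t[i - 1]))
    if not crossings:
        raise MaturationError("late trace never rises above the early trace")
    if len(crossings) == 1:
        return float(crossings[0])
    half = 0.5 * late.values.max()
    above = np.nonzero(late.values >= half)[0]
    t_half = late.times[above[0]] if above.size else late.times[-1]
    return float(min(crossings, key=lambda c: abs(c - t_half)))


def _snap_index(rel_t: float, step: float) -> int:
    """Nearest grid index with ties toward earlier time."""
    return int(np.ceil(rel_t / step - 0.5))


def align_and_average(events: list[MaturationEvent], roles,
                      grid_step: float = 2.0, min_frac: float = 0.5,
                      window: tuple[float, float] = (-40.0, 45.0),
                      require_window: bool = True) -> AlignedAverage:
    """Align events at their midpoints and average per role.

    Each trace is re-indexed to ``rel_time = t - midpoint``, snapped to the
    nearest point of a common grid (ties toward earlier time), and averaged
    across events.  Events whose traces do not cover ``window`` are dropped
    when ``require_window`` is set; grid points where fewer than
    ``min_frac`` of the events contribute are discarded.
    """
    if not events:
        raise MaturationError("no maturation events to average")
    usable = []
    for ev in events:
        covers = all(
            ev.traces[role].times[0] - ev.midpoint <= window[0]
            and ev.traces[role].times[-1] - ev.midpoint >= window[1]
            for role in roles if role in ev.traces)
        if (not require_window) or covers:
            usable.append(ev)
    if not usable:
        raise MaturationError("no event covers the alignment window")

    lo = min(_snap_index(ev.traces[role].times[0] - ev.midpoint, grid_step)
             for ev in usable for role in roles if role in ev.traces)
    hi = max(_snap_index(ev.traces[role].times[-1] - ev.midpoint, grid_step)
             for ev in usable for role in roles if role in ev.traces)
    grid = np.arange(lo, hi + 1)
    rel_times = grid * grid_step

    mean, sem, counts = {}, {}, {}
    keep = np.zeros(grid.size, dtype=bool)
    for role in roles:
        acc = [[] for _ in grid]
        for ev in usable:
            if role not in ev.traces:
                continue
            tr = ev.traces[role]
            per_point: dict[int, list[float]] = {}
            for t, v in zip(tr.times, tr.values):
                gi = _snap_index(t - ev.midpoint, grid_step) - lo
                if 0 <= gi < grid.size:
                    per_point.setdefault(gi, []).append(float(v))
            for gi, vals in per_point.items():
                acc[gi].append(float(np.mean(vals)))
        n = np.array([len(a) for a in acc])
        mu = np.array([np.mean(a) if a else np.nan for a in acc])
        se = np.array([np.std(a, ddof=1) / np.sqrt(len(a))
                       if len(a) >= 2 else np.nan for a in acc])
        mean[role], sem[role], counts[role] = mu, se, n
        keep |= n >= max(np.ceil(min_frac * len(usable)), 1)
    return AlignedAverage(
        rel_times=rel_times[keep],
        mean={r: mean[r][keep] for r in roles},
        sem={r: sem[r][keep] for r in roles},
        n_events=len(usable),
        counts={r: counts[r][keep] for r in roles})


def _sustained_crossings(trace: Trace, level: float,
                         min_run: int = 2):
    """(arrival, departure) of the first/last sustained excursion above
    ``level``, linearly interpolated; None where never crossed."""
    v, t = trace.values, trace.times
    above = v > level
    runs = []
    i = 0
    while i < v.size:
        if above[i]:
            j = i
            while j + 1 < v.size and above[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not runs:
        return None, None
    i0, _ = runs[0]
    if i0 == 0:
        arrival = float(t[0])
    else:
        frac = (level - v[i0 - 1]) / (v[i0] - v[i0 - 1])
        arrival = float(t[i0 - 1] + frac * (t[i0] - t[i0 - 1]))
    _, j1 = runs[-1]
    if j1 == v.size - 1:
        departure = float(t[-1])
    else:
        frac = (v[j1] - level) / (v[j1] - v[j1 + 1])
        departure = float(t[j1] + frac * (t[j1 + 1] - t[j1]))
    return arrival, departure


def adaptor_timing(reference: Trace, others: list[Trace],
                   level: float = 0.5) -> dict[str, dict[str, float | None]]:
    """Arrival/departure offsets of adaptor traces relative to a reference.

    Arrival is the first time a (peak-normalized) trace exceeds ``level``
    for at least two consecutive frames, linearly interpolated at the
    crossing; departure is the last sustained fall below ``level``.
    Offsets are ``other - reference`` in seconds; traces that never cross
    the level report ``None`` for both offsets.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    ref_arr, ref_dep = _sustained_crossings(reference, level)
    if ref_arr is None:
        raise MaturationError("reference trace never crosses the level")
    out = {}
    for tr in others:
        arr, dep = _sustained_crossings(tr, level)
        out[tr.role or tr.structure] = {
            "arrival_offset": None if arr is None else arr - ref_arr,
            "departure_offset": None if dep is None else dep - ref_dep,
        }
    return out
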