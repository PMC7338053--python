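"""Matplotlib figures for the standard analyses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .bursts import BurstTable
from .delivery import DeliveryRecord, PopulationSummary
from .maturation import AlignedAverage

__all__ = ["plot_aligned_average", "plot_delivery", "plot_burst_timeline"]


def plot_aligned_average(avg: AlignedAverage, title: str = ""):
    """Aligned population-average maturation traces with SEM bands."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for role in avg.mean:
        mu, se = avg.mean[role], avg.sem[role]
        ax.plot(avg.rel_times, mu, label=role)
        ok = ~np.isnan(se)
        ax.fill_between(avg.rel_times[ok], (mu - se)[ok], (mu + se)[ok],
                        alpha=0.25)
    ax.axvline(0.0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("time from transition midpoint (s)")
    ax.set_ylabel("normalized fluorescence (a.u.)")
    ax.set_title(title or f"{avg.n_events} maturation events")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_delivery(records: list[DeliveryRecord],
                  summary: PopulationSummary | None = None):
    """Per-cell vacuolar accumulation curves plus the population mean."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for rec in records:
        ax.plot(rec.vac_trace.times / 60.0, rec.vac_trace.values,
                color="0.7", lw=0.8)
    if summary is not None:
        ax.plot(summary.times / 60.0, summary.mean, color="C3", lw=2,
                label=f"mean of {summary.n_cells} cells")
        ax.fill_between(summary.times / 60.0, summary.mean - summary.sem,
                        summary.mean + summary.sem, color="C3", alpha=0.3)
        ax.legend(fontsize=8)
    ax.set_xlabel("time after cargo release (min)")
    ax.set_ylabel("vacuolar cargo fluorescence (a.u.)")
    fig.tight_layout()
    return fig


def plot_burst_timeline(times: np.ndarray, remaining: np.ndarray,
                        table: BurstTable, vac: np.ndarray | None = None):
    """Remaining PVE cargo at interval boundaries with bursts marked."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(times, remaining, "-o", ms=2, label="PVE cargo")
    if vac is not None:
        ax.plot(times, vac, "-s", ms=2, color="C2", label="vacuole cargo")
    bursts = table.intervals[table.intervals["is_burst"]]
    for _, row in bursts.iterrows():
        ax.axvspan(row["t_start"], row["t_end"], color="C1", alpha=0.3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cargo fluorescence (a.u.)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
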