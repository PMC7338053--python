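"""Compartment-level kinetic simulation of Golgi-to-vacuole cargo traffic.

The simulator produces per-compartment *true* fluorescence time series (the
ground truth against which the quantification pipeline is validated) for a
single yeast cell containing maturing Golgi cisternae, vacuole-attached PVE
(prevacuolar endosome) compartments and one vacuole.

Kinetic model
-------------
* Each cisterna matures once: the early marker decays and the late marker
  rises as smooth logistic curves crossing at the transition midpoint; the
  late marker later departs at the end of the cisterna's lifetime.
* The GGA adaptor channel follows the late marker; the AP-1 adaptor channel
  is the same curve shifted later in arrival and departure.
* Cisternal cargo is constant until the transition midpoint.  After the
  midpoint it decays exponentially (``wildtype`` / ``apl4_null``), rises
  transiently and then persists (``vps10_null``; recycling of cargo from
  older cisternae injects signal from outside the cell's ledger), or
  persists unchanged (``gga_null``: exit is abolished).
* Cargo leaving cisternae is credited to the PVE compartments; each active
  PVE loses cargo continuously at ``pve_leak_rate`` plus instantaneous
  kiss-and-run bursts at Poisson-scheduled times with truncated-normal
  fractions.  Everything a PVE loses is credited to the vacuole in the same
  frame, so bleach-free simulations conserve total cargo exactly (up to the
  deliberate ``vps10_null`` overshoot).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from .config import KineticConfig, OpticsConfig
from .trace import Trace
from . import roles as R

__all__ = [
    "Compartment",
    "CompartmentTimeline",
    "GroundTruth",
    "simulate_timeline",
    "apply_photobleach",
    "simulate_delivery_cohort",
    "DEFAULT_DELAY_MIXTURE",
    "mixture_tail_mass",
]

#: default per-cell appearance-onset-delay mixture for delivery movies, in
#: seconds: 65% of cells start delivering 4-14 min after the cargo wave is
#: released, 35% only after 16-29 min (the slow tail seen in cell
#: populations).  Component format: (weight, low_s, high_s), uniform within.
DEFAULT_DELAY_MIXTURE = ((0.65, 240.0, 840.0), (0.35, 960.0, 1740.0))


def mixture_tail_mass(mixture, t: float) -> float:
    """True probability that an onset delay drawn from ``mixture`` exceeds t."""
    mass = 0.0
    for w, lo, hi in mixture:
        if t <= lo:
            mass += w
        elif t < hi:
            mass += w * (hi - t) / (hi - lo)
    return mass


@dataclass
class Compartment:
    """One compartment's geometry and true per-channel signal series."""

    id: str
    klass: str  # "cisterna" | "pve" | "vacuole"
    centers: np.ndarray  # (n_frames, 3) in um, (z, y, x)
    radius: float  # um
    signal: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "klass": self.klass,
            "centers": np.asarray(self.centers).tolist(),
            "radius": float(self.radius),
            "signal": {k: np.asarray(v).tolist()
                       for k, v in self.signal.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Compartment":
        return cls(id=d["id"], klass=d["klass"],
                   centers=np.asarray(d["centers"], dtype=float),
                   radius=float(d["radius"]),
                   signal={k: np.asarray(v, dtype=float)
                           for k, v in d["signal"].items()})


@dataclass
class CompartmentTimeline:
    """All compartments of one simulated cell plus the time base."""

    times: np.ndarray  # s, one per frame
    compartments: list[Compartment]

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def roles(self) -> list[str]:
        present = set()
        for c in self.compartments:
            present.update(c.signal)
        return [r for r in R.CANONICAL_ORDER if r in present]

    def compartment(self, comp_id: str) -> Compartment:
        for c in self.compartments:
            if c.id == comp_id:
                return c
        raise KeyError(comp_id)

    def by_class(self, klass: str) -> list[Compartment]:
        return [c for c in self.compartments if c.klass == klass]

    def total_cargo(self) -> np.ndarray:
        """Per-frame summed true cargo over all compartments."""
        tot = np.zeros(self.n_frames)
        for c in self.compartments:
            if R.CARGO in c.signal:
                tot += c.signal[R.CARGO]
        return tot

    def trace(self, comp_id: str, role: str) -> Trace:
        """Ground-truth trace of one compartment and channel role."""
        c = self.compartment(comp_id)
        return Trace(structure=comp_id, role=role, times=self.times.copy(),
                     values=c.signal[role].copy(), klass=c.klass)

    def to_dict(self) -> dict:
        return {"times": self.times.tolist(),
                "compartments": [c.to_dict() for c in self.compartments]}

    @classmethod
    def from_dict(cls, d: dict) -> "CompartmentTimeline":
        return cls(times=np.asarray(d["times"], dtype=float),
                   compartments=[Compartment.from_dict(c)
                                 for c in d["compartments"]])


@dataclass
class GroundTruth:
    """Truth ledger for recovery tests.

    ``burst_schedule`` maps PVE id to a list of (time_s, fraction) pairs;
    ``transition_midpoint`` maps cisterna id to the true early-to-late
    crossing time; adaptor arrival/departure times are per cisterna and per
    adaptor role.
    """

    burst_schedule: dict[str, list[tuple[float, float]]]
    transition_midpoint: dict[str, float]
    adaptor_arrival: dict[str, dict[str, float]]
    adaptor_departure: dict[str, dict[str, float]]
    conserved_total_cargo: float
    quiescent: dict[str, bool] = field(default_factory=dict)
    onset_delay: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "burst_schedule": {k: [[float(t), float(f)] for t, f in v]
                               for k, v in self.burst_schedule.items()},
            "transition_midpoint": {k: float(v) for k, v in
                                    self.transition_midpoint.items()},
            "adaptor_arrival": self.adaptor_arrival,
            "adaptor_departure": self.adaptor_departure,
            "conserved_total_cargo": float(self.conserved_total_cargo),
            "quiescent": self.quiescent,
            "onset_delay": {k: float(v) for k, v in self.onset_delay.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            burst_schedule={k: [(float(t), float(f)) for t, f in v]
                            for k, v in d["burst_schedule"].items()},
            transition_midpoint=dict(d["transition_midpoint"]),
            adaptor_arrival={k: dict(v) for k, v in
                             d["adaptor_arrival"].items()},
            adaptor_departure={k: dict(v) for k, v in
                               d["adaptor_departure"].items()},
            conserved_total_cargo=float(d["conserved_total_cargo"]),
            quiescent=dict(d.get("quiescent", {})),
            onset_delay=dict(d.get("onset_delay", {})),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _sample_truncnorm(rng, mean, sd, lo, hi) -> float:
    """Rejection sampler; support is validated to have nonzero mass."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    # pathological (support far in the tail): fall back to the clipped mean
    return float(np.clip(mean, lo, hi))


def _poisson_times(rng, rate: float, t0: float, t1: float) -> list[float]:
    out = []
    if rate <= 0 or t1 <= t0:
        return out
    t = t0
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= t1:
            return out
        out.append(float(t))


def _place_positions(rng, optics: OpticsConfig, kin: KineticConfig,
                     n_cisternae: int, n_pve: int):
    """Choose static compartment centers (um, z/y/x) within the field."""
    fz, fy, fx = optics.field_um
    center = np.array([fz / 2.0, fy / 2.0, fx / 2.0])
    vac_center = center.copy()

    pve_centers = []
    for i in range(n_pve):
        phi = 2.0 * np.pi * (i + rng.uniform(0.1, 0.9)) / max(n_pve, 1)
        alpha = rng.uniform(-0.2, 0.2)  # keep PVEs near the equatorial plane
        dist = kin.vacuole_radius_um + rng.uniform(0.5, 1.0) * kin.pve_radius_um
        offset = np.array([dist * np.sin(alpha),
                           dist * np.cos(alpha) * np.sin(phi),
                           dist * np.cos(alpha) * np.cos(phi)])
        pve_centers.append(vac_center + offset)

    cis_centers = []
    margin = 3.0 * (optics.psf_sigma_xy / 1000.0) + kin.cisterna_radius_um
    max_r = min(fy, fx) / 2.0 - margin
    min_r = kin.vacuole_radius_um + 2.0 * kin.pve_radius_um + 0.3
    for i in range(n_cisternae):
        phi = 2.0 * np.pi * (i + rng.uniform(0.1, 0.9)) / max(n_cisternae, 1)
        dist = max(min(max_r, min_r + rng.uniform(0.0, 0.8)), 0.2)
        dz = rng.uniform(-0.3, 0.3)
        cis_centers.append(vac_center
                           + np.array([dz, dist * np.sin(phi),
                                       dist * np.cos(phi)]))
    return vac_center, pve_centers, cis_centers


def simulate_timeline(kinetics: KineticConfig, optics: OpticsConfig,
                      n_cisternae: int, n_pve: int, seed: int,
                      onset_delays=None) -> tuple[CompartmentTimeline,
                                                  GroundTruth]:
    """Simulate per-compartment true signal series and the truth ledger.

    Parameters
    ----------
    onset_delays : sequence of float, optional
        Per-PVE delivery onset delays in seconds (the PVE accepts cargo but
        delivers nothing before its onset).  Defaults to 0 for every PVE;
        quiescent PVEs (drawn with ``kinetics.quiescent_prob``) never
        deliver regardless.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(optics.n_frames) * optics.frame_interval
    nT = optics.n_frames
    T = optics.duration
    kin = kinetics

    if onset_delays is None:
        onset_delays = [0.0] * n_pve
    if len(onset_delays) != n_pve:
        raise ValueError("onset_delays must have one entry per PVE")

    vac_center, pve_centers, cis_centers = _place_positions(
        rng, optics, kin, n_cisternae, n_pve)

    tau = kin.marker_slope_tau
    A = kin.marker_amplitude
    k_exit = kin.effective_cargo_exit_rate

    compartments: list[Compartment] = []
    midpoints: dict[str, float] = {}
    arrivals: dict[str, dict[str, float]] = {}
    departures: dict[str, dict[str, float]] = {}

    # --- Golgi cisternae -------------------------------------------------
    lo_m, hi_m = 40.0, T - 45.0  # event window [-40, +45] inside the movie
    # when the movie is long enough, also keep the whole cisterna life
    # (including the delayed adaptor departure) inside it
    lo_full = max(lo_m, kin.transition_midpoint_frac * kin.cisterna_lifetime)
    hi_full = min(hi_m, T - (1.0 - kin.transition_midpoint_frac)
                  * kin.cisterna_lifetime - kin.adaptor_offset_departure
                  - 3.0 * tau)
    cis_cargo_analytic = []
    for i in range(n_cisternae):
        cid = f"cis{i}"
        if hi_full > lo_full:
            m = rng.uniform(lo_full, hi_full)
        elif hi_m > lo_m:
            m = rng.uniform(lo_m, hi_m)
        else:
            m = T / 2.0
        birth = m - kin.transition_midpoint_frac * kin.cisterna_lifetime
        t_dep = birth + kin.cisterna_lifetime
        early = A * _logistic((m - times) / tau)
        late = A * _logistic((times - m) / tau) * _logistic(
            (t_dep - times) / tau)
        gga = late.copy()
        ap1 = (A * _logistic((times - (m + kin.adaptor_offset_arrival)) / tau)
               * _logistic((t_dep + kin.adaptor_offset_departure - times)
                           / tau))
        c0 = kin.cisterna_cargo * rng.uniform(0.8, 1.2)
        if kin.mode == "vps10_null":
            bump_center = m + 0.2 * (t_dep - m)
            bump_sd = max((t_dep - m) / 4.0, 1e-9)
            cargo = c0 * (1.0 + (kin.cargo_overshoot - 1.0)
                          * np.exp(-0.5 * ((times - bump_center)
                                           / bump_sd) ** 2))
        else:
            cargo = np.where(times < m, c0,
                             c0 * np.exp(-k_exit * (times - m)))
        cis_cargo_analytic.append(cargo)
        compartments.append(Compartment(
            id=cid, klass="cisterna",
            centers=np.tile(cis_centers[i], (nT, 1)),
            radius=kin.cisterna_radius_um,
            signal={R.CARGO: cargo.copy(), R.EARLY_GOLGI: early,
                    R.LATE_GOLGI: late, R.ADAPTOR_GGA: gga,
                    R.ADAPTOR_AP1: ap1}))
        midpoints[cid] = float(m)
        arrivals[cid] = {R.ADAPTOR_GGA: float(m),
                         R.ADAPTOR_AP1: float(m + kin.adaptor_offset_arrival)}
        departures[cid] = {R.ADAPTOR_GGA: float(t_dep),
                           R.ADAPTOR_AP1: float(
                               t_dep + kin.adaptor_offset_departure)}

    # --- PVE compartments ------------------------------------------------
    quiescent: dict[str, bool] = {}
    schedules: dict[str, list[tuple[float, float]]] = {}
    onset: dict[str, float] = {}
    pve_sig: dict[str, np.ndarray] = {}
    pve_marker: dict[str, np.ndarray] = {}
    for j in range(n_pve):
        pid = f"pve{j}"
        q = bool(rng.uniform() < kin.quiescent_prob)
        quiescent[pid] = q
        onset[pid] = float(onset_delays[j])
        if q:
            schedules[pid] = []
        else:
            btimes = _poisson_times(rng, kin.burst_rate, onset[pid], T)
            lo, hi = kin.burst_fraction_support
            schedules[pid] = [
                (t, _sample_truncnorm(rng, kin.burst_fraction_mean,
                                      kin.burst_fraction_sd, lo, hi))
                for t in btimes]
        pve_sig[pid] = np.zeros(nT)
        pve_sig[pid][0] = kin.pve_initial_cargo
        # Vps8-like marker: fluctuates multiplicatively but never vanishes
        x = np.zeros(nT)
        innov_sd = kin.pve_marker_fluct_sd * np.sqrt(
            max(1.0 - kin.pve_marker_fluct_rho ** 2, 0.0))
        x[0] = rng.normal(0.0, kin.pve_marker_fluct_sd)
        for i in range(1, nT):
            x[i] = kin.pve_marker_fluct_rho * x[i - 1] + rng.normal(
                0.0, innov_sd)
        pve_marker[pid] = A * np.exp(x - kin.pve_marker_fluct_sd ** 2 / 2.0)

    # --- step the transfer ledger ---------------------------------------
    vac = np.zeros(nT)
    vac[0] = kin.vacuole_initial_cargo
    dt = optics.frame_interval
    leak_keep = np.exp(-kin.pve_leak_rate * dt)
    for i in range(1, nT):
        released = 0.0
        for cargo in cis_cargo_analytic:
            released += max(cargo[i - 1] - cargo[i], 0.0)
        per_pve = released / n_pve if n_pve else 0.0
        vac_gain = 0.0 if n_pve else released
        t_lo, t_hi = times[i - 1], times[i]
        for j in range(n_pve):
            pid = f"pve{j}"
            p = pve_sig[pid][i - 1] + per_pve
            if quiescent[pid] or t_hi <= onset[pid]:
                pve_sig[pid][i] = p
                continue
            p_new = p * leak_keep
            for (tb, fb) in schedules[pid]:
                if t_lo < tb <= t_hi:
                    p_new *= (1.0 - fb)
            vac_gain += p - p_new
            pve_sig[pid][i] = p_new
        vac[i] = vac[i - 1] + vac_gain

    for j in range(n_pve):
        pid = f"pve{j}"
        compartments.append(Compartment(
            id=pid, klass="pve", centers=np.tile(pve_centers[j], (nT, 1)),
            radius=kin.pve_radius_um,
            signal={R.CARGO: pve_sig[pid], R.PVE: pve_marker[pid]}))

    compartments.append(Compartment(
        id="vacuole", klass="vacuole", centers=np.tile(vac_center, (nT, 1)),
        radius=kin.vacuole_radius_um,
        signal={R.CARGO: vac,
                R.VACUOLE_MEMBRANE: np.full(
                    nT, A * kin.vacuole_marker_scale)}))

    timeline = CompartmentTimeline(times=times, compartments=compartments)
    truth = GroundTruth(
        burst_schedule=schedules,
        transition_midpoint=midpoints,
        adaptor_arrival=arrivals,
        adaptor_departure=departures,
        conserved_total_cargo=float(timeline.total_cargo()[0]),
        quiescent=quiescent,
        onset_delay=onset,
    )
    return timeline, truth


def apply_photobleach(timeline: CompartmentTimeline, efficiency: float,
                      at_frame: int) -> CompartmentTimeline:
    """Photobleach everything except the PVE compartments at one frame.

    Emulates the pre-acquisition bleach protocol: a region of interest
    covering all fluorescent structures except the PVE compartments is
    illuminated at full laser power.  At ``at_frame`` the true cargo signal
    of every non-PVE compartment (vacuole interior included) is reduced by
    ``efficiency``; PVE cargo and all marker channels are untouched, and
    cargo arriving in the vacuole after the bleach is not bleached (the
    bleached vacuolar pool is subtracted, later increments are preserved).
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    if not 0 <= at_frame < timeline.n_frames:
        raise ValueError("at_frame outside the movie")
    out = copy.deepcopy(timeline)
    for comp in out.compartments:
        if comp.klass == "pve" or R.CARGO not in comp.signal:
            continue
        cargo = comp.signal[R.CARGO]
        if comp.klass == "vacuole":
            pool = efficiency * cargo[at_frame]
            cargo[at_frame:] = np.maximum(cargo[at_frame:] - pool, 0.0)
        else:
            cargo[at_frame:] *= (1.0 - efficiency)
    return out


def simulate_delivery_cohort(n_cells: int, kinetics: KineticConfig,
                             optics: OpticsConfig,
                             delay_mixture=DEFAULT_DELAY_MIXTURE,
                             seed: int = 0, n_pve: int = 1,
                             bleach_efficiency: float = 1.0):
    """Simulate a population of cells for the whole-cell delivery analysis.

    Each cell holds preloaded PVE compartment(s) plus the vacuole; the
    per-cell delivery onset delay is drawn from ``delay_mixture`` (weighted
    uniform components, seconds).  Before acquisition the leaked vacuolar
    cargo pool is photobleached (``bleach_efficiency``), emulating the
    pre-movie vacuole bleach of the imaging protocol.  In ``vps10_null``
    mode no cargo ever reaches the PVE/vacuole system, emulating receptor
    loss.

    Returns a list of ``(timeline, truth)`` pairs; ``truth.onset_delay``
    holds each cell's true onset.
    """
    rng = np.random.default_rng(seed)
    weights = np.array([w for w, _, _ in delay_mixture], dtype=float)
    weights = weights / weights.sum()
    out = []
    kin = kinetics
    if kin.mode == "vps10_null":
        import dataclasses
        kin = dataclasses.replace(kin, pve_initial_cargo=0.0,
                                  vacuole_initial_cargo=0.0)
    for _ in range(n_cells):
        comp = rng.choice(len(delay_mixture), p=weights)
        _, lo, hi = delay_mixture[comp]
        delay = float(rng.uniform(lo, hi))
        cell_seed = int(rng.integers(0, 2 ** 31 - 1))
        tl, truth = simulate_timeline(kin, optics, n_cisternae=0,
                                      n_pve=n_pve, seed=cell_seed,
                                      onset_delays=[delay] * n_pve)
        if bleach_efficiency > 0:
            tl = apply_photobleach(tl, bleach_efficiency, 0)
        out.append((tl, truth))
    return out
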