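"""Acquisition and kinetic configuration.

Two dataclasses parameterize every simulation: :class:`OpticsConfig` describes
the confocal acquisition (voxel pitch, stack depth, frame interval, PSF and
noise model), and :class:`KineticConfig` describes the compartment-level cargo
kinetics (cisternal maturation, Golgi exit, PVE leak and kiss-and-run bursts).
Defaults follow the acquisition geometry and kinetics of live-cell yeast
imaging: 60-80 nm pixels, 0.25-0.30 um Z-steps, 20-30 optical sections, 2 s
stacks for maturation movies, 60 s stacks for hour-long delivery movies and
5 s stacks for 10 min burst movies.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

__all__ = [
    "OpticsConfig",
    "KineticConfig",
    "RunConfig",
    "ConfigError",
    "MODES",
    "maturation_optics",
    "delivery_optics",
    "burst_optics",
]

MODES = ("wildtype", "vps10_null", "apl4_null", "gga_null")


class ConfigError(ValueError):
    """A configuration field is out of its documented range."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class OpticsConfig:
    """Confocal acquisition geometry, gain and noise.

    Parameters
    ----------
    voxel_xy : float
        XY pixel pitch in nanometres (60-80 nm by default).
    voxel_z : float
        Z-step in micrometres (0.25-0.30 um by default).
    n_z : int
        Optical sections per stack (20-30 by default).
    frame_interval : float
        Seconds between consecutive Z-stacks.
    n_frames : int
        Number of stacks in the movie.
    n_y, n_x : int
        Field size in pixels.
    psf_sigma_xy : float
        Lateral Gaussian PSF sigma in nanometres.
    psf_sigma_z : float
        Axial Gaussian PSF sigma in micrometres.
    photon_gain : float
        Detected photons (counts) per unit of true signal.
    read_noise_sd : float
        Gaussian read noise standard deviation in counts.
    background : float
        Flat cytoplasmic background offset in counts.
    seed : int
        Seed for rendering noise.
    """

    voxel_xy: float = 70.0
    voxel_z: float = 0.28
    n_z: int = 24
    frame_interval: float = 2.0
    n_frames: int = 46
    n_y: int = 96
    n_x: int = 96
    psf_sigma_xy: float = 90.0
    psf_sigma_z: float = 0.30
    photon_gain: float = 50.0
    read_noise_sd: float = 2.0
    background: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voxel_xy", "voxel_z", "frame_interval", "psf_sigma_xy",
                     "psf_sigma_z", "photon_gain"):
            _require(getattr(self, name) > 0, name, "must be positive")
        for name in ("n_z", "n_frames", "n_y", "n_x"):
            _require(int(getattr(self, name)) >= 1, name, "must be >= 1")
        _require(self.read_noise_sd >= 0, "read_noise_sd", "must be >= 0")
        _require(self.background >= 0, "background", "must be >= 0")

    @property
    def duration(self) -> float:
        """Movie duration in seconds (time of the last frame)."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def voxel_um(self) -> tuple[float, float, float]:
        """Voxel size as (z, y, x) in micrometres."""
        return (self.voxel_z, self.voxel_xy / 1000.0, self.voxel_xy / 1000.0)

    @property
    def field_um(self) -> tuple[float, float, float]:
        """Field extent as (z, y, x) in micrometres."""
        vz, vy, vx = self.voxel_um
        return (self.n_z * vz, self.n_y * vy, self.n_x * vx)


@dataclass(frozen=True)
class KineticConfig:
    """Compartment-level cargo kinetics.

    The four modes emulate the genetic backgrounds of the experiments:
    ``wildtype`` (cargo exits maturing cisternae from the early-to-late
    transition onward), ``vps10_null`` (no sorting receptor: cargo overshoots
    transiently, then persists and is eventually secreted), ``apl4_null``
    (AP-1 inactive: indistinguishable Golgi exit from wildtype) and
    ``gga_null`` (GGAs inactive: cargo exit abolished, shallower marker
    transitions).

    Rates are per second.  ``burst_rate`` is the Poisson intensity of
    kiss-and-run transfer events per active PVE compartment; per-burst
    fractions are drawn from a normal truncated to ``burst_fraction_support``.
    """

    mode: str = "wildtype"
    cisterna_lifetime: float = 180.0
    transition_midpoint_frac: float = 0.5
    cargo_exit_rate: float = 0.015
    cargo_overshoot: float = 1.3
    pve_leak_rate: float = 5.0e-4
    burst_rate: float = 1.0 / 300.0
    burst_fraction_mean: float = 0.375
    burst_fraction_sd: float = 0.12
    burst_fraction_support: tuple[float, float] = (0.16, 0.95)
    quiescent_prob: float = 0.2
    adaptor_offset_arrival: float = 30.0
    adaptor_offset_departure: float = 12.0
    # geometry and amplitudes (arbitrary units)
    vacuole_radius_um: float = 1.2
    pve_radius_um: float = 0.2
    cisterna_radius_um: float = 0.25
    cisterna_cargo: float = 100.0
    pve_initial_cargo: float = 100.0
    vacuole_initial_cargo: float = 30.0
    marker_amplitude: float = 100.0
    # the vacuole carries far more membrane marker than a punctum; its total
    # shell signal is marker_amplitude * vacuole_marker_scale
    vacuole_marker_scale: float = 20.0
    # PVE marker fluctuation (multiplicative AR(1) on log scale)
    pve_marker_fluct_sd: float = 0.10
    pve_marker_fluct_rho: float = 0.8

    def __post_init__(self) -> None:
        _require(self.mode in MODES, "mode", f"must be one of {MODES}")
        _require(self.cisterna_lifetime > 0, "cisterna_lifetime",
                 "must be positive")
        _require(0.0 < self.transition_midpoint_frac < 1.0,
                 "transition_midpoint_frac", "must be in (0, 1)")
        for name in ("cargo_exit_rate", "pve_leak_rate", "burst_rate"):
            _require(getattr(self, name) >= 0, name, "rate must be >= 0")
        lo = self.burst_fraction_mean - 2.0 * self.burst_fraction_sd
        hi = self.burst_fraction_mean + 2.0 * self.burst_fraction_sd
        _require(0.0 < lo and hi < 1.0, "burst_fraction_mean",
                 "mean +/- 2 sd must lie within (0, 1)")
        slo, shi = self.burst_fraction_support
        _require(0.0 < slo < shi < 1.0, "burst_fraction_support",
                 "support must lie within (0, 1)")
        _require(0.0 <= self.quiescent_prob <= 1.0, "quiescent_prob",
                 "must be in [0, 1]")
        _require(self.cargo_overshoot >= 1.0, "cargo_overshoot",
                 "must be >= 1")
        _require(1.0 <= self.vacuole_radius_um <= 1.5, "vacuole_radius_um",
                 "must be in [1.0, 1.5]")
        for name in ("pve_radius_um", "cisterna_radius_um"):
            _require(getattr(self, name) > 0, name, "must be positive")

    @property
    def effective_cargo_exit_rate(self) -> float:
        """Cargo exit rate actually applied; forced to 0 without GGAs."""
        return 0.0 if self.mode == "gga_null" else self.cargo_exit_rate

    @property
    def marker_slope_tau(self) -> float:
        """Logistic time constant of marker transitions (s).

        Without GGAs the Vrg4/Sec7 arrival and departure curves are
        abnormally shallow; that is emulated by doubling the time constant.
        """
        tau = self.cisterna_lifetime / 12.0
        return 2.0 * tau if self.mode == "gga_null" else tau


def maturation_optics(**overrides) -> OpticsConfig:
    """Acquisition preset for maturation movies: 2 s stacks over >= 90 s."""
    base = dict(frame_interval=2.0, n_frames=46)
    base.update(overrides)
    return OpticsConfig(**base)


def delivery_optics(**overrides) -> OpticsConfig:
    """Acquisition preset for delivery movies: 60 s stacks over 60 min."""
    base = dict(frame_interval=60.0, n_frames=61)
    base.update(overrides)
    return OpticsConfig(**base)


def burst_optics(**overrides) -> OpticsConfig:
    """Acquisition preset for burst movies: 5 s stacks over 10 min."""
    base = dict(frame_interval=5.0, n_frames=121)
    base.update(overrides)
    return OpticsConfig(**base)


_EXPERIMENTS = ("maturation", "delivery", "bursts")
_OPTICS_PRESETS = {
    "maturation": maturation_optics,
    "delivery": delivery_optics,
    "bursts": burst_optics,
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the downstream analyses."""

    burst_interval: float = 10.0
    burst_threshold: float = 0.15
    burst_floor_frac: float = 0.02
    appearance_frac: float = 0.05
    detect_k: float = 3.0
    timing_level: float = 0.5
    min_voxels: int = 10
    max_displacement_um: float = 0.5

    def __post_init__(self) -> None:
        _require(self.burst_interval > 0, "burst_interval", "must be > 0")
        _require(0.0 < self.burst_threshold < 1.0, "burst_threshold",
                 "must be in (0, 1)")
        _require(0.0 <= self.burst_floor_frac < 1.0, "burst_floor_frac",
                 "must be in [0, 1)")
        _require(0.0 <= self.appearance_frac <= 1.0, "appearance_frac",
                 "must be in [0, 1]")
        _require(self.detect_k >= 0, "detect_k", "must be >= 0")
        _require(0.0 < self.timing_level < 1.0, "timing_level",
                 "must be in (0, 1)")
        _require(self.min_voxels >= 1, "min_voxels", "must be >= 1")
        _require(self.max_displacement_um > 0, "max_displacement_um",
                 "must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (mirrors the YAML schema)."""

    experiment: str = "bursts"
    seed: int = 0
    n_cisternae: int = 0
    n_pve: int = 2
    n_cells: int = 1
    photobleach_efficiency: float = 0.0
    optics: OpticsConfig = field(default_factory=burst_optics)
    kinetics: KineticConfig = field(default_factory=KineticConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        _require(self.experiment in _EXPERIMENTS, "experiment",
                 f"must be one of {_EXPERIMENTS}")
        _require(self.n_cisternae >= 0, "n_cisternae", "must be >= 0")
        _require(self.n_pve >= 0, "n_pve", "must be >= 0")
        _require(self.n_cells >= 1, "n_cells", "must be >= 1")
        _require(0.0 <= self.photobleach_efficiency <= 1.0,
                 "photobleach_efficiency", "must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        experiment = raw.get("experiment", "bursts")
        optics_raw = dict(raw.pop("optics", {}) or {})
        kin_raw = dict(raw.pop("kinetics", {}) or {})
        ana_raw = dict(raw.pop("analysis", {}) or {})
        if "burst_fraction_support" in kin_raw:
            kin_raw["burst_fraction_support"] = tuple(
                kin_raw["burst_fraction_support"])
        preset = _OPTICS_PRESETS.get(experiment, burst_optics)
        try:
            optics = preset(**optics_raw)
            kinetics = KineticConfig(**kin_raw)
            analysis = AnalysisConfig(**ana_raw)
            return cls(optics=optics, kinetics=kinetics, analysis=analysis,
                       **raw)
        except TypeError as exc:  # unknown field name
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinetics"]["burst_fraction_support"] = list(
            d["kinetics"]["burst_fraction_support"])
        return d

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for provenance logging."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]
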