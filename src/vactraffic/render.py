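"""Forward imaging model: timeline -> synthetic confocal movie.

Punctate compartments (cisternae, PVEs) are rendered as anisotropic 3-D
Gaussians whose integrated intensity equals ``photon_gain * true_signal``;
the structure radius broadens the PSF in quadrature.  The vacuole membrane
marker is rendered as a PSF-blurred spherical shell and luminal vacuole
cargo as a PSF-smoothed filled sphere, both normalized so that integrated
intensity is preserved.  With noise enabled, voxel counts are Poisson
distributed about the noiseless image (plus the flat background) with
additive Gaussian read noise, clipped at zero.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

from .config import OpticsConfig
from .movie import Movie
from .timeline import Compartment, CompartmentTimeline
from . import roles as R

__all__ = ["render_movie", "GeometryError"]


class GeometryError(ValueError):
    """A structure's support does not fit inside the imaging field."""


def _sigma_vox(optics: OpticsConfig, radius_um: float):
    """Effective Gaussian sigma (z, y, x) in voxels for a punctum."""
    vz, vy, vx = optics.voxel_um
    s_xy = math.hypot(optics.psf_sigma_xy / 1000.0, radius_um / 2.0)
    s_z = math.hypot(optics.psf_sigma_z, radius_um / 2.0)
    return (s_z / vz, s_xy / vy, s_xy / vx)


def _patch_slices(center_vox, half, shape):
    sl, lo_ofs = [], []
    for c, h, n in zip(center_vox, half, shape):
        lo = max(int(math.floor(c - h)), 0)
        hi = min(int(math.ceil(c + h)) + 1, n)
        sl.append(slice(lo, hi))
        lo_ofs.append(lo)
    return tuple(sl), lo_ofs


def _add_gaussian(vol, center_um, sigma_vox, amplitude, voxel_um,
                  check_support=True):
    """Add a normalized anisotropic Gaussian of total mass ``amplitude``."""
    shape = vol.shape
    cvox = [c / v for c, v in zip(center_um, voxel_um)]
    if check_support:
        for c, s, n in zip(cvox, sigma_vox, shape):
            if c - 3.0 * s < -0.5 or c + 3.0 * s > n - 0.5:
                raise GeometryError(
                    "punctum support (3 sigma) exceeds the field")
    half = [4.0 * s + 1.0 for s in sigma_vox]
    sl, lo = _patch_slices(cvox, half, shape)
    axes = []
    for ax in range(3):
        idx = np.arange(sl[ax].start, sl[ax].stop, dtype=float)
        axes.append(np.exp(-0.5 * ((idx - cvox[ax]) / sigma_vox[ax]) ** 2))
    kern = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None,
                                                                     None, :]
    total = kern.sum()
    if total <= 0:
        return
    vol[sl] += amplitude * kern / total


def _radial_kernel(shape, center_um, voxel_um, fn, max_r_um):
    """Evaluate ``fn(distance_um)`` on the patch within ``max_r_um``."""
    cvox = [c / v for c, v in zip(center_um, voxel_um)]
    half = [max_r_um / v + 1.0 for v in voxel_um]
    sl, _ = _patch_slices(cvox, half, shape)
    zz = (np.arange(sl[0].start, sl[0].stop) - cvox[0]) * voxel_um[0]
    yy = (np.arange(sl[1].start, sl[1].stop) - cvox[1]) * voxel_um[1]
    xx = (np.arange(sl[2].start, sl[2].stop) - cvox[2]) * voxel_um[2]
    d = np.sqrt(zz[:, None, None] ** 2 + yy[None, :, None] ** 2
                + xx[None, None, :] ** 2)
    return sl, fn(d)


def _add_shell(vol, center_um, radius_um, sigma_um, amplitude, voxel_um):
    """Spherical shell of mass ``amplitude`` (membrane marker)."""
    max_r = radius_um + 4.0 * sigma_um
    sl, kern = _radial_kernel(vol.shape, center_um, voxel_um,
                              lambda d: np.exp(-0.5 * ((d - radius_um)
                                                       / sigma_um) ** 2),
                              max_r)
    total = kern.sum()
    if total <= 0:
        return
    vol[sl] += amplitude * kern / total


def _add_sphere(vol, center_um, radius_um, sigma_um, amplitude, voxel_um):
    """PSF-smoothed filled sphere of mass ``amplitude`` (luminal cargo)."""
    max_r = radius_um + 4.0 * sigma_um
    sl, kern = _radial_kernel(
        vol.shape, center_um, voxel_um,
        lambda d: 0.5 * (1.0 - erf((d - radius_um)
                                   / (math.sqrt(2.0) * sigma_um))),
        max_r)
    total = kern.sum()
    if total <= 0:
        return
    vol[sl] += amplitude * kern / total


def _render_compartment(vol, center, comp: Compartment, role: str,
                        value: float, optics: OpticsConfig) -> None:
    voxel_um = optics.voxel_um
    psf_mean_um = (optics.psf_sigma_xy / 1000.0 * 2 + optics.psf_sigma_z) / 3.0
    if comp.klass == "vacuole":
        if role in R.VACUOLE_SHELL_ROLES:
            _add_shell(vol, center, comp.radius, psf_mean_um, value, voxel_um)
        else:  # luminal content
            _add_sphere(vol, center, comp.radius, psf_mean_um, value,
                        voxel_um)
    else:
        sigma = _sigma_vox(optics, comp.radius)
        _add_gaussian(vol, center, sigma, value, voxel_um)


def render_movie(timeline: CompartmentTimeline, optics: OpticsConfig,
                 noise: bool = False) -> Movie:
    """Render a timeline into a T x C x Z x Y x X movie.

    The channel list is the set of roles present in the timeline, in
    canonical order.  Rendering is linear in the true signal; with ``noise``
    the Poisson/read-noise model of ``optics`` is applied using
    ``optics.seed``.
    """
    if timeline.n_frames != optics.n_frames:
        raise ValueError("timeline frames do not match optics.n_frames")
    role_list = timeline.roles
    shape = (optics.n_frames, len(role_list), optics.n_z, optics.n_y,
             optics.n_x)
    data = np.zeros(shape, dtype=float)
    for ci, role in enumerate(role_list):
        for comp in timeline.compartments:
            if role not in comp.signal:
                continue
            series = comp.signal[role]
            for t in range(optics.n_frames):
                value = optics.photon_gain * float(series[t])
                if value <= 0:
                    continue
                _render_compartment(data[t, ci], comp.centers[t], comp,
                                    role, value, optics)
    if optics.background:
        data += optics.background
    if noise:
        rng = np.random.default_rng(optics.seed)
        data = rng.poisson(data).astype(float)
        if optics.read_noise_sd > 0:
            data += rng.normal(0.0, optics.read_noise_sd, size=data.shape)
        data = np.clip(data, 0.0, None)
    roles = {i: r for i, r in enumerate(role_list)}
    return Movie(data=data, roles=roles, times=timeline.times.copy(),
                 voxel=(optics.voxel_xy, optics.voxel_xy, optics.voxel_z))
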