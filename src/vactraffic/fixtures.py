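"""Small deterministic movies for testing and demos.

Every fixture is generated programmatically from a seed: a tiny field
(<= 32 x 64 x 64 voxels, <= 60 frames) keeps segmentation and rendering
fast while exercising the full simulate -> render -> quantify path.
"""

from __future__ import annotations

import dataclasses

from .config import KineticConfig, OpticsConfig
from .render import render_movie
from .timeline import simulate_timeline

__all__ = ["make_fixtures", "small_burst_optics", "small_maturation_optics",
           "small_delivery_optics", "small_kinetics"]


def small_burst_optics(**kw) -> OpticsConfig:
    base = dict(n_z=14, n_y=64, n_x=64, voxel_xy=80.0, voxel_z=0.30,
                frame_interval=5.0, n_frames=60)
    base.update(kw)
    return OpticsConfig(**base)


def small_maturation_optics(**kw) -> OpticsConfig:
    base = dict(n_z=14, n_y=64, n_x=64, voxel_xy=80.0, voxel_z=0.30,
                frame_interval=2.0, n_frames=46)
    base.update(kw)
    return OpticsConfig(**base)


def small_delivery_optics(**kw) -> OpticsConfig:
    base = dict(n_z=14, n_y=64, n_x=64, voxel_xy=80.0, voxel_z=0.30,
                frame_interval=60.0, n_frames=31)
    base.update(kw)
    return OpticsConfig(**base)


def small_kinetics(**kw) -> KineticConfig:
    base = dict(vacuole_radius_um=1.0, quiescent_prob=0.0)
    base.update(kw)
    return KineticConfig(**base)


def make_fixtures(seed: int = 0) -> dict:
    """Generate the small test movies with their ground truth.

    Returns a dict with ``burst``, ``delivery`` and ``maturation`` entries,
    each ``{"timeline", "truth", "movie", "optics", "kinetics"}``.  The
    fixture set is a pure function of the seed.
    """
    out = {}

    kin_b = small_kinetics()
    opt_b = small_burst_optics(seed=seed)
    tl, truth = simulate_timeline(kin_b, opt_b, n_cisternae=0, n_pve=1,
                                  seed=seed)
    out["burst"] = {"timeline": tl, "truth": truth,
                    "movie": render_movie(tl, opt_b, noise=False),
                    "optics": opt_b, "kinetics": kin_b}

    kin_d = small_kinetics(pve_leak_rate=1.0 / 600.0, burst_rate=0.0)
    opt_d = small_delivery_optics(seed=seed + 1)
    tl, truth = simulate_timeline(kin_d, opt_d, n_cisternae=0, n_pve=1,
                                  seed=seed + 1)
    out["delivery"] = {"timeline": tl, "truth": truth,
                       "movie": render_movie(tl, opt_d, noise=False),
                       "optics": opt_d, "kinetics": kin_d}

    kin_m = small_kinetics(vacuole_radius_um=1.0)
    opt_m = small_maturation_optics(seed=seed + 2)
    tl, truth = simulate_timeline(kin_m, opt_m, n_cisternae=1, n_pve=1,
                                  seed=seed + 2)
    out["maturation"] = {"timeline": tl, "truth": truth,
                         "movie": render_movie(tl, opt_m, noise=False),
                         "optics": opt_m, "kinetics": kin_m}
    return out
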