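"""Marker-masked fluorescence measurement on 4D movies.

The measurement rule mirrors live-cell practice: one channel (a compartment
marker such as Vph1 or Vps8) defines a 3-D mask, and another channel (the
cargo) is measured inside it.  Structures are segmented per frame by
Gaussian smoothing plus automated thresholding, labeled with 26-connected
components, linked over time by greedy nearest-centroid matching, and
summed inside their masks with a per-frame median background correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .movie import Movie
from .trace import Trace
from . import roles as R

__all__ = [
    "StructureMask",
    "Track",
    "segment_structures",
    "link_structures",
    "measure_in_mask",
    "extract_traces",
    "fraction_compartments_with_cargo",
    "cargo_distribution_by_class",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class StructureMask:
    """A labeled 3-D region for one structure at one frame."""

    frame: int
    label: int
    voxels: np.ndarray  # boolean Z x Y x X
    klass: str  # marker role that defined the mask
    centroid_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class Track:
    """A structure followed over consecutive frames."""

    id: str
    masks: dict[int, StructureMask] = field(default_factory=dict)

    @property
    def frames(self) -> list[int]:
        return sorted(self.masks)

    def __len__(self) -> int:
        return len(self.masks)


def _smooth_sigma_vox(movie: Movie, smooth_sigma: float):
    vz, vy, vx = movie.voxel_um
    return (smooth_sigma * vy / vz, smooth_sigma, smooth_sigma)


def _centroid_um(mask: np.ndarray, voxel_um) -> tuple[float, float, float]:
    idx = np.argwhere(mask)
    c = idx.mean(axis=0)
    return tuple(float(ci * vi) for ci, vi in zip(c, voxel_um))


def _threshold(smoothed: np.ndarray, policy) -> float:
    if policy == "otsu":
        return float(threshold_otsu(smoothed))
    if isinstance(policy, (tuple, list)) and policy[0] == "mean_k_sigma":
        k = float(policy[1])
        return float(smoothed.mean() + k * smoothed.std())
    raise ValueError(f"unknown threshold policy {policy!r}")


def segment_structures(movie: Movie, role: str, frame: int,
                       policy="otsu", min_voxels: int = 10,
                       smooth_sigma: float = 1.0, dilate: int = 0,
                       fill_shell: bool | None = None,
                       erode: int = 0) -> list[StructureMask]:
    """Segment marker-defined structures in one frame.

    The channel is Gaussian-smoothed (sigma in XY voxels, scaled for the Z
    anisotropy) and thresholded by ``policy`` (Otsu by default, or
    ``("mean_k_sigma", k)`` for dim channels); 26-connected components with
    at least ``min_voxels`` voxels are kept.  For the vacuole-membrane role
    (or when ``fill_shell`` is true) each shell component is morphologically
    closed and filled so the mask includes the lumen; ``erode`` then shrinks
    it, which is useful when the measured content is strictly luminal.
    ``dilate`` grows punctate masks to capture the blurred periphery of a
    spot.  An empty list (no structures) is a valid result.
    """
    vol = movie.channel(role)[frame].astype(float)
    if np.ptp(vol) == 0:
        return []
    sm = ndi.gaussian_filter(vol, sigma=_smooth_sigma_vox(movie,
                                                          smooth_sigma))
    if np.ptp(sm) == 0:
        return []
    thr = _threshold(sm, policy)
    binary = sm > thr
    if not binary.any():
        return []
    if fill_shell is None:
        fill_shell = role == R.VACUOLE_MEMBRANE
    labels, n = ndi.label(binary, structure=_CONN26)
    voxel_um = movie.voxel_um
    out = []
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() < min_voxels:
            continue
        if fill_shell:
            comp = ndi.binary_closing(comp, structure=_CONN26, iterations=2)
            comp = ndi.binary_fill_holes(comp)
            for z in range(comp.shape[0]):  # open poles at the stack limits
                comp[z] = ndi.binary_fill_holes(comp[z])
        if dilate:
            comp = ndi.binary_dilation(comp, structure=_CONN26,
                                       iterations=dilate)
        if erode:
            eroded = ndi.binary_erosion(comp, structure=_CONN26,
                                        iterations=erode)
            if eroded.sum() >= min_voxels:
                comp = eroded
        if comp.sum() < min_voxels:
            continue
        out.append(StructureMask(frame=frame, label=lab, voxels=comp,
                                 klass=role,
                                 centroid_um=_centroid_um(comp, voxel_um)))
    # canonical, input-order-independent ordering
    out.sort(key=lambda m: m.centroid_um)
    for i, m in enumerate(out):
        m.label = i
    return out


def _overlap(a: StructureMask, b: StructureMask) -> int:
    return int(np.logical_and(a.voxels, b.voxels).sum())


def link_structures(masks_per_frame: list[list[StructureMask]],
                    max_displacement_um: float = 0.5,
                    min_duration: int = 1) -> list[Track]:
    """Link per-frame masks into tracks by greedy nearest-centroid matching.

    Candidate matches between consecutive frames are considered in order of
    increasing centroid distance, ties broken by larger voxel overlap and
    then by lower (canonical) label, making the linking deterministic and
    independent of input label order.  Masks farther than
    ``max_displacement_um`` start new tracks; tracks shorter than
    ``min_duration`` frames are discarded.
    """
    tracks: list[Track] = []
    open_tracks: dict[int, Track] = {}  # current-frame mask id -> track
    counter = 0
    prev_masks: list[StructureMask] = []
    for fi, masks in enumerate(masks_per_frame):
        masks = sorted(masks, key=lambda m: m.centroid_um)
        new_open: dict[int, Track] = {}
        if prev_masks and masks:
            cands = []
            for pi, pm in enumerate(prev_masks):
                if pi not in open_tracks:
                    continue
                for mi, m in enumerate(masks):
                    d = math.dist(pm.centroid_um, m.centroid_um)
                    if d <= max_displacement_um:
                        cands.append((d, -_overlap(pm, m), m.label, pi, mi))
            cands.sort()
            used_prev, used_new = set(), set()
            for d, _, _, pi, mi in cands:
                if pi in used_prev or mi in used_new:
                    continue
                used_prev.add(pi)
                used_new.add(mi)
                tr = open_tracks[pi]
                tr.masks[fi] = masks[mi]
                new_open[mi] = tr
        for mi, m in enumerate(masks):
            if mi in new_open:
                continue
            tr = Track(id=f"{m.klass}-{counter}", masks={fi: m})
            counter += 1
            tracks.append(tr)
            new_open[mi] = tr
        open_tracks = new_open
        prev_masks = masks
    return [t for t in tracks if len(t) >= min_duration]


def _background_stats(channel_vol: np.ndarray, masks) -> tuple[float, float]:
    """Median and SD of the channel outside all masks in the frame."""
    outside = np.ones(channel_vol.shape, dtype=bool)
    for m in masks:
        outside &= ~m.voxels
    vals = channel_vol[outside]
    if vals.size == 0:
        return 0.0, 0.0
    return float(np.median(vals)), float(vals.std())


def measure_in_mask(movie: Movie, role: str, mask: StructureMask,
                    all_masks=None, background: str = "median_outside",
                    exclude: np.ndarray | None = None) -> float:
    """Background-corrected integrated intensity of ``role`` inside a mask.

    The background per voxel is the median of the channel outside all masks
    of the frame (``all_masks``, defaulting to just this mask); the result
    is ``sum_inside - n_voxels * background``, floored at 0.  ``exclude``
    removes voxels (e.g. belonging to an overlapping structure of another
    class) from the mask before measuring.
    """
    voxels = mask.voxels
    if exclude is not None:
        voxels = np.logical_and(voxels, ~exclude)
    if not voxels.any():
        raise ValueError("mask is empty")
    vol = movie.channel(role)[mask.frame].astype(float)
    if background == "median_outside":
        bg, _ = _background_stats(vol, all_masks if all_masks is not None
                                  else [mask])
    elif background == "none":
        bg = 0.0
    else:
        raise ValueError(f"unknown background policy {background!r}")
    total = float(vol[voxels].sum()) - voxels.sum() * bg
    return max(total, 0.0)


def _segment_all_frames(movie: Movie, role: str, **seg_kw):
    return [segment_structures(movie, role, t, **seg_kw)
            for t in range(movie.n_frames)]


def extract_traces(movie: Movie, mask_role: str, measure_roles,
                   policy="otsu", min_voxels: int = 10,
                   smooth_sigma: float = 1.0, dilate: int = 0,
                   erode: int = 0,
                   max_displacement_um: float = 0.5, min_duration: int = 1,
                   exclude_role: str | None = None,
                   exclude_dilate: int = 3,
                   exclude_policy=None) -> tuple[list[Trace],
                                                 list[Track]]:
    """Per-structure, per-role traces from marker-defined tracked masks.

    ``exclude_role`` optionally segments a second marker (e.g. the PVE
    marker when measuring luminal vacuole cargo) and removes its dilated
    masks from this role's masks before measuring, so adjacent structures
    do not contaminate each other.  Frames where a tracked structure is
    missing terminate that trace's span (traces carry no gaps).
    """
    masks_per_frame = _segment_all_frames(
        movie, mask_role, policy=policy, min_voxels=min_voxels,
        smooth_sigma=smooth_sigma, dilate=dilate, erode=erode)
    excl_per_frame = None
    if exclude_role is not None:
        excl_per_frame = _segment_all_frames(
            movie, exclude_role,
            policy=exclude_policy if exclude_policy is not None else policy,
            min_voxels=min_voxels,
            smooth_sigma=smooth_sigma, dilate=exclude_dilate)
    tracks = link_structures(masks_per_frame, max_displacement_um,
                             min_duration)
    traces: list[Trace] = []
    for tr in tracks:
        frames = tr.frames
        # longest contiguous run (gaps terminate the span)
        runs, start = [], frames[0]
        for a, b in zip(frames, frames[1:]):
            if b != a + 1:
                runs.append((start, a))
                start = b
        runs.append((start, frames[-1]))
        f0, f1 = max(runs, key=lambda r: r[1] - r[0])
        span = list(range(f0, f1 + 1))
        for role in measure_roles:
            vals = []
            for fi in span:
                mask = tr.masks[fi]
                frame_masks = list(masks_per_frame[fi])
                exclude = None
                if excl_per_frame is not None:
                    frame_masks += excl_per_frame[fi]
                    if excl_per_frame[fi]:
                        exclude = np.zeros(mask.voxels.shape, dtype=bool)
                        for em in excl_per_frame[fi]:
                            exclude |= em.voxels
                if exclude is not None and not np.logical_and(
                        mask.voxels, ~exclude).any():
                    # structure fully covered by an excluded neighbour
                    vals.append(0.0)
                    continue
                vals.append(measure_in_mask(movie, role, mask,
                                            all_masks=frame_masks,
                                            exclude=exclude))
            traces.append(Trace(structure=tr.id, role=role,
                                times=movie.times[span],
                                values=np.asarray(vals), klass=mask_role))
    return traces, tracks


def fraction_compartments_with_cargo(movie: Movie, cargo_role: str,
                                     masks_per_frame, detect_k: float = 3.0):
    """Fraction of compartments with detectable cargo, per frame.

    A compartment contains detectable cargo at a frame when its in-mask
    mean cargo intensity exceeds the background mean plus ``detect_k``
    background standard deviations (an automated stand-in for manual
    scoring).  Frames with zero compartments yield NaN (missing), not 0.
    """
    cargo = movie.channel(cargo_role)
    out = np.full(movie.n_frames, np.nan)
    for fi, masks in enumerate(masks_per_frame):
        if not masks:
            continue
        vol = cargo[fi].astype(float)
        outside = np.ones(vol.shape, dtype=bool)
        for m in masks:
            outside &= ~m.voxels
        bg_vals = vol[outside]
        bg_mean = float(bg_vals.mean()) if bg_vals.size else 0.0
        bg_sd = float(bg_vals.std()) if bg_vals.size else 0.0
        thr = bg_mean + detect_k * bg_sd
        detected = sum(float(vol[m.voxels].mean()) > thr for m in masks)
        out[fi] = detected / len(masks)
    return out


def cargo_distribution_by_class(movie: Movie, cargo_role: str,
                                masks_by_class: dict[str, list[StructureMask]],
                                frame: int,
                                priority: list[str] | None = None) -> dict:
    """Percentage of whole-cell cargo fluorescence per compartment class.

    Overlapping masks are resolved by ``priority`` order (first wins).
    Percentages over the listed classes plus ``"unassigned"`` sum to 100
    exactly.  Raises if the whole-cell background-corrected cargo total is
    not positive.
    """
    vol = movie.channel(cargo_role)[frame].astype(float)
    all_masks = [m for ms in masks_by_class.values() for m in ms]
    bg, _ = _background_stats(vol, all_masks)
    total = float(vol.sum()) - vol.size * bg
    if total <= 0:
        raise ValueError("whole-cell cargo total is not positive")
    if priority is None:
        priority = list(masks_by_class)
    claimed = np.zeros(vol.shape, dtype=bool)
    pct: dict[str, float] = {}
    for klass in priority:
        union = np.zeros(vol.shape, dtype=bool)
        for m in masks_by_class.get(klass, []):
            union |= m.voxels
        union &= ~claimed
        claimed |= union
        value = float(vol[union].sum()) - union.sum() * bg
        pct[klass] = 100.0 * max(value, 0.0) / total
    pct["unassigned"] = 100.0 - sum(pct.values())
    return pct
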