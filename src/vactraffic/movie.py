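"""5-D movie container and OME-TIFF round-trip.

Movies are stored as T x C x Z x Y x X arrays with a channel-role map, frame
times and voxel geometry.  On disk they are OME-TIFF files (axes TCZYX,
16-bit unsigned) whose OME metadata carries the channel roles as channel
names, the voxel sizes and the frame interval; the simulation ground truth
travels in a JSON sidecar (see :mod:`vactraffic.timeline`).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = ["Movie", "MovieIOError", "write_movie", "read_movie"]


class MovieIOError(IOError):
    """Missing or malformed movie metadata."""


@dataclass
class Movie:
    """A multi-channel 4D movie.

    Attributes
    ----------
    data : ndarray, shape (T, C, Z, Y, X)
        Nonnegative intensities (a.u.; uint16 when read from disk).
    roles : dict[int, str]
        Channel index -> channel role.
    times : ndarray
        Frame times in seconds, strictly increasing.
    voxel : tuple
        (xy_nm, xy_nm, z_um) voxel geometry.
    """

    data: np.ndarray
    roles: dict[int, str]
    times: np.ndarray
    voxel: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("movie data must be 5-D (T, C, Z, Y, X)")
        if self.data.shape[0] != self.times.size:
            raise ValueError("times must match the number of frames")
        if self.data.shape[1] != len(self.roles):
            raise ValueError("roles must map every channel")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_um(self) -> tuple[float, float, float]:
        """(z, y, x) voxel size in micrometres."""
        return (self.voxel[2], self.voxel[0] / 1000.0, self.voxel[1] / 1000.0)

    def channel_index(self, role: str) -> int:
        for idx, r in self.roles.items():
            if r == role:
                return idx
        raise KeyError(f"channel role {role!r} not present")

    def channel(self, role: str) -> np.ndarray:
        """The (T, Z, Y, X) stack for one channel role."""
        return self.data[:, self.channel_index(role)]

    def frame_interval(self) -> float:
        if self.times.size < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))


def write_movie(movie: Movie, path) -> None:
    """Write an OME-TIFF with the role map embedded as channel names."""
    data = movie.data
    if data.dtype != np.uint16:
        data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(
            np.uint16)
    names = [movie.roles[i] for i in range(data.shape[1])]
    xy_um = movie.voxel[0] / 1000.0
    metadata = {
        "axes": "TCZYX",
        "Channel": {"Name": names},
        "PhysicalSizeX": xy_um, "PhysicalSizeXUnit": "um",
        "PhysicalSizeY": movie.voxel[1] / 1000.0, "PhysicalSizeYUnit": "um",
        "PhysicalSizeZ": movie.voxel[2], "PhysicalSizeZUnit": "um",
        "TimeIncrement": movie.frame_interval(),
        "TimeIncrementUnit": "s",
    }
    tifffile.imwrite(path, data, ome=True, photometric="minisblack",
                     metadata=metadata)


def _ome_pixels(ome_xml: str):
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Image/ome:Pixels", ns)
    if pixels is None:
        raise MovieIOError("no OME Pixels element found")
    channels = pixels.findall("ome:Channel", ns)
    return pixels, channels


def read_movie(path) -> Movie:
    """Read an OME-TIFF written by :func:`write_movie`.

    A file without a channel-role map (OME channel names) is rejected: the
    analyses cannot guess which channel is cargo and which is a marker.
    """
    with tifffile.TiffFile(path) as tf:
        if tf.ome_metadata is None:
            raise MovieIOError("file has no OME metadata")
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        pixels, channels = _ome_pixels(tf.ome_metadata)

    # expand to 5-D TCZYX regardless of squeezed singleton axes
    full = "TCZYX"
    for i, ax in enumerate(full):
        if ax not in axes:
            data = np.expand_dims(data, i)
            axes = axes[:i] + ax + axes[i:]
    order = [axes.index(ax) for ax in full]
    data = np.transpose(data, order)

    names = [ch.get("Name") for ch in channels]
    if len(names) != data.shape[1] or any(not n for n in names):
        raise MovieIOError("channel-role map missing from OME metadata")
    roles = {i: str(n) for i, n in enumerate(names)}

    def _fget(attr, default=None):
        v = pixels.get(attr)
        if v is None:
            if default is None:
                raise MovieIOError(f"OME metadata lacks {attr}")
            return default
        return float(v)

    xy_nm = _fget("PhysicalSizeX") * 1000.0
    yy_nm = _fget("PhysicalSizeY") * 1000.0
    z_um = _fget("PhysicalSizeZ")
    dt = _fget("TimeIncrement", default=1.0)
    times = np.arange(data.shape[0]) * dt
    return Movie(data=data, roles=roles, times=times,
                 voxel=(xy_nm, yy_nm, z_um))
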