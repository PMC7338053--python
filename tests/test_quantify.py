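"""Segmentation, linking and masked measurement.

The forward renderer serves as the oracle: spots of known integrated
intensity are rendered noiselessly and the measured values are compared to
the generating truth.
"""

import numpy as np
import pytest

from vactraffic import roles as R
from vactraffic.config import OpticsConfig
from vactraffic.movie import Movie
from vactraffic.quantify import (StructureMask, cargo_distribution_by_class,
                                 extract_traces,
                                 fraction_compartments_with_cargo,
                                 link_structures, measure_in_mask,
                                 segment_structures)
from vactraffic.render import render_movie
from vactraffic.timeline import Compartment, CompartmentTimeline


def _opt(**kw):
    base = dict(n_z=14, n_y=48, n_x=48, voxel_xy=80.0, voxel_z=0.30,
                n_frames=1, background=0.0, photon_gain=10.0,
                read_noise_sd=0.0, seed=0)
    base.update(kw)
    return OpticsConfig(**base)


def _render(compartments, optics):
    n = optics.n_frames
    tl = CompartmentTimeline(times=np.arange(n) * optics.frame_interval,
                             compartments=compartments)
    return render_movie(tl, optics, noise=False)


def _spot(cid, center, value, n_frames=1, radius=0.25, role=R.CARGO,
          klass="cisterna"):
    centers = np.tile(np.asarray(center, dtype=float), (n_frames, 1))
    return Compartment(cid, klass, centers=centers, radius=radius,
                       signal={role: np.full(n_frames, float(value))})


def _flood_fill(binary, start):
    """Brute-force 26-connected flood fill (independent oracle)."""
    from collections import deque
    out = np.zeros_like(binary)
    q = deque([start])
    out[start] = True
    while q:
        z, y, x = q.popleft()
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    n = (z + dz, y + dy, x + dx)
                    if (0 <= n[0] < binary.shape[0]
                            and 0 <= n[1] < binary.shape[1]
                            and 0 <= n[2] < binary.shape[2]
                            and binary[n] and not out[n]):
                        out[n] = True
                        q.append(n)
    return out


class TestSegmentation:
    def test_all_zero_frame_yields_empty_list(self):
        opt = _opt()
        movie = _render([_spot("a", (2.1, 1.9, 1.9), 0.0)], opt)
        assert segment_structures(movie, R.CARGO, 0) == []

    def test_single_spot_matches_flood_fill_oracle(self):
        opt = _opt()
        movie = _render([_spot("a", (2.1, 1.9, 1.9), 50.0)], opt)
        masks = segment_structures(movie, R.CARGO, 0)
        assert len(masks) == 1
        vol = movie.channel(R.CARGO)[0]
        peak = np.unravel_index(np.argmax(vol), vol.shape)
        assert masks[0].voxels[peak]
        # rebuild the same component by flood fill from the peak over the
        # same smoothed/thresholded binary image
        from scipy import ndimage as ndi
        from skimage.filters import threshold_otsu
        sm = ndi.gaussian_filter(vol, sigma=(80.0 / 300.0, 1.0, 1.0))
        binary = sm > threshold_otsu(sm)
        oracle = _flood_fill(binary, peak)
        assert np.array_equal(masks[0].voxels, oracle)

    def test_two_spots_two_masks(self):
        opt = _opt()
        movie = _render([_spot("a", (2.1, 1.3, 1.3), 50.0),
                         _spot("b", (2.1, 2.6, 2.6), 50.0)], opt)
        masks = segment_structures(movie, R.CARGO, 0)
        assert len(masks) == 2

    def test_min_voxels_filters_components(self):
        opt = _opt()
        movie = _render([_spot("a", (2.1, 1.9, 1.9), 50.0)], opt)
        assert segment_structures(movie, R.CARGO, 0,
                                  min_voxels=10 ** 6) == []

    def test_vacuole_shell_fill_includes_lumen(self):
        opt = _opt()
        vac = Compartment("v", "vacuole",
                          centers=np.array([[2.1, 1.9, 1.9]]), radius=1.0,
                          signal={R.VACUOLE_MEMBRANE: np.array([2000.0])})
        movie = _render([vac], opt)
        filled = segment_structures(movie, R.VACUOLE_MEMBRANE, 0)
        hollow = segment_structures(movie, R.VACUOLE_MEMBRANE, 0,
                                    fill_shell=False)
        assert len(filled) == 1
        assert filled[0].n_voxels >= sum(m.n_voxels for m in hollow)
        # lumen centre voxel is inside the filled mask
        assert filled[0].voxels[7, 24, 24]


class TestLinking:
    def _mask(self, frame, center_vox, label=0, shape=(6, 24, 24)):
        vox = np.zeros(shape, dtype=bool)
        z, y, x = center_vox
        vox[z - 1:z + 2, y - 1:y + 2, x - 1:x + 2] = True
        m = StructureMask(frame=frame, label=label, voxels=vox, klass=R.PVE)
        m.centroid_um = (z * 0.3, y * 0.08, x * 0.08)
        return m

    def test_stationary_spot_one_track(self):
        frames = [[self._mask(t, (3, 12, 12))] for t in range(10)]
        tracks = link_structures(frames, max_displacement_um=0.5)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_two_separated_spots_do_not_swap(self):
        """Exhaustive 2x2 assignment oracle: both greedy and brute force
        keep each spot on its own track."""
        frames = []
        for t in range(6):
            frames.append([self._mask(t, (3, 6, 6)),
                           self._mask(t, (3, 18, 18), label=1)])
        tracks = link_structures(frames, max_displacement_um=0.5)
        assert len(tracks) == 2
        for tr in tracks:
            cents = [tr.masks[f].centroid_um for f in tr.frames]
            assert len({c for c in cents}) == 1  # never moved

    def test_vanishing_spot_ends_track(self):
        frames = [[self._mask(t, (3, 12, 12))] for t in range(5)]
        frames += [[] for _ in range(3)]
        tracks = link_structures(frames, max_displacement_um=0.5)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1, 2, 3, 4]

    def test_jump_beyond_max_displacement_starts_new_track(self):
        frames = [[self._mask(0, (3, 6, 6))], [self._mask(1, (3, 18, 18))]]
        tracks = link_structures(frames, max_displacement_um=0.3)
        assert len(tracks) == 2

    def test_permutation_invariance_of_input_order(self):
        def build(swap):
            frames = []
            for t in range(4):
                pair = [self._mask(t, (3, 6, 6)),
                        self._mask(t, (3, 18, 18), label=1)]
                frames.append(pair[::-1] if swap else pair)
            return link_structures(frames, max_displacement_um=0.5)

        a, b = build(False), build(True)
        key = lambda tr: tr.masks[0].centroid_um
        for ta, tb in zip(sorted(a, key=key), sorted(b, key=key)):
            assert ta.frames == tb.frames
            assert all(ta.masks[f].centroid_um == tb.masks[f].centroid_um
                       for f in ta.frames)


class TestMeasurement:
    def test_zero_region_zero_background_measures_zero(self):
        opt = _opt()
        movie = _render([_spot("a", (2.1, 1.9, 1.9), 0.0)], opt)
        vox = np.zeros(movie.data.shape[2:], dtype=bool)
        vox[5:8, 10:14, 10:14] = True
        mask = StructureMask(frame=0, label=0, voxels=vox, klass=R.CARGO)
        assert measure_in_mask(movie, R.CARGO, mask) == 0.0

    def test_uniform_image_cancels_exactly(self):
        data = np.full((1, 1, 6, 16, 16), 7.0)
        movie = Movie(data=data, roles={0: R.CARGO}, times=np.array([0.0]),
                      voxel=(80.0, 80.0, 0.3))
        vox = np.zeros((6, 16, 16), dtype=bool)
        vox[2:4, 4:8, 4:8] = True
        mask = StructureMask(frame=0, label=0, voxels=vox, klass=R.CARGO)
        assert measure_in_mask(movie, R.CARGO, mask) == 0.0

    def test_rendered_spot_recovered_within_5pct(self):
        opt = _opt(background=2.0)
        movie = _render([_spot("a", (2.1, 1.9, 1.9), 50.0)], opt)
        masks = segment_structures(movie, R.CARGO, 0, dilate=3)
        assert len(masks) == 1
        value = measure_in_mask(movie, R.CARGO, masks[0], all_masks=masks)
        assert value == pytest.approx(500.0, rel=0.05)

    def test_empty_mask_raises(self):
        opt = _opt()
        movie = _render([_spot("a", (2.1, 1.9, 1.9), 50.0)], opt)
        mask = StructureMask(frame=0, label=0,
                             voxels=np.zeros(movie.data.shape[2:], bool),
                             klass=R.CARGO)
        with pytest.raises(ValueError):
            measure_in_mask(movie, R.CARGO, mask)


class TestExtractTraces:
    def test_measurement_linearity_under_intensity_scaling(self):
        opt = _opt(n_frames=5, frame_interval=5.0, background=2.0)
        movie = _render([_spot("a", (2.1, 1.9, 1.9), 50.0, n_frames=5)],
                        opt)
        traces, _ = extract_traces(movie, R.CARGO, [R.CARGO], dilate=2)
        scaled = Movie(data=movie.data * 3.0, roles=movie.roles,
                       times=movie.times, voxel=movie.voxel)
        traces3, _ = extract_traces(scaled, R.CARGO, [R.CARGO], dilate=2)
        assert len(traces) == len(traces3) == 1
        np.testing.assert_allclose(traces3[0].values,
                                   3.0 * traces[0].values, rtol=1e-9)

    def test_self_measurement_returns_marker_signal(self, burst_fixture):
        movie = burst_fixture["movie"]
        traces, _ = extract_traces(movie, R.PVE, [R.PVE], dilate=2)
        assert traces and traces[0].role == R.PVE
        assert np.all(traces[0].values > 0)

    def test_noise_off_traces_match_ground_truth(self, burst_fixture):
        movie = burst_fixture["movie"]
        tl = burst_fixture["timeline"]
        pve_traces, _ = extract_traces(movie, R.PVE, [R.CARGO], dilate=2)
        vac_traces, _ = extract_traces(movie, R.VACUOLE_MEMBRANE,
                                       [R.CARGO], erode=1,
                                       exclude_role=R.PVE)
        for tr, comp in [(pve_traces[0], "pve0"),
                         (vac_traces[0], "vacuole")]:
            truth = tl.trace(comp, R.CARGO)
            t = np.interp(tr.times, truth.times, truth.values)
            rms = np.sqrt(np.mean((tr.values / tr.values.max()
                                   - t / t.max()) ** 2))
            assert rms <= 0.05

    def test_bleached_movie_vacuole_trace_drops(self):
        from vactraffic.timeline import apply_photobleach, \
            simulate_timeline
        from vactraffic.config import KineticConfig
        opt = _opt(n_frames=10, frame_interval=5.0, background=2.0,
                   n_y=64, n_x=64)
        kin = KineticConfig(quiescent_prob=0.0, burst_rate=0.0,
                            pve_leak_rate=0.0, vacuole_radius_um=1.0)
        tl, _ = simulate_timeline(kin, opt, 0, 1, seed=3)
        bleached = apply_photobleach(tl, 0.5, at_frame=5)
        movie = render_movie(bleached, opt, noise=False)
        traces, _ = extract_traces(movie, R.VACUOLE_MEMBRANE, [R.CARGO],
                                   erode=1, exclude_role=R.PVE)
        v = traces[0].values
        assert v[5] == pytest.approx(0.5 * v[4], rel=0.05)


class TestDetectionAndDistribution:
    def test_fraction_detected_all_or_nothing(self):
        opt = _opt(n_frames=1, background=2.0)
        bright = _render([_spot("a", (2.1, 1.3, 1.3), 50.0),
                          _spot("b", (2.1, 2.6, 2.6), 50.0)], opt)
        masks = [segment_structures(bright, R.CARGO, 0, dilate=1)]
        assert len(masks[0]) == 2
        frac = fraction_compartments_with_cargo(bright, R.CARGO, masks)
        assert frac[0] == 1.0
        # same masks, but measure an empty (noise-free background) channel
        dark_data = np.full_like(bright.data, 2.0)
        dark = Movie(data=np.concatenate([bright.data, dark_data], axis=1),
                     roles={0: R.CARGO, 1: "dark"}, times=bright.times,
                     voxel=bright.voxel)
        frac = fraction_compartments_with_cargo(dark, "dark", masks)
        assert frac[0] == 0.0

    def test_zero_compartments_reported_missing(self):
        opt = _opt()
        movie = _render([_spot("a", (2.1, 1.9, 1.9), 50.0)], opt)
        frac = fraction_compartments_with_cargo(movie, R.CARGO, [[]])
        assert np.isnan(frac[0])

    def test_cargo_split_recovered_and_partition_exact(self):
        opt = _opt(n_y=64, n_x=64, background=2.0)
        movie = _render([_spot("a", (2.1, 1.6, 1.6), 70.0),
                         _spot("b", (2.1, 3.5, 3.5), 30.0)], opt)
        masks = segment_structures(movie, R.CARGO, 0, dilate=3)
        assert len(masks) == 2
        by_class = {"A": [masks[0]], "B": [masks[1]]}
        pct = cargo_distribution_by_class(movie, R.CARGO, by_class, 0,
                                          priority=["A", "B"])
        assert pct["A"] == pytest.approx(70.0, abs=2.0)
        assert pct["B"] == pytest.approx(30.0, abs=2.0)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_total_cargo_is_error(self):
        data = np.full((1, 1, 6, 16, 16), 2.0)
        movie = Movie(data=data, roles={0: R.CARGO}, times=np.array([0.0]),
                      voxel=(80.0, 80.0, 0.3))
        vox = np.zeros((6, 16, 16), dtype=bool)
        vox[2:4, 4:8, 4:8] = True
        mask = StructureMask(frame=0, label=0, voxels=vox, klass="A")
        with pytest.raises(ValueError):
            cargo_distribution_by_class(movie, R.CARGO, {"A": [mask]}, 0)
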