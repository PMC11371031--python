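import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from beamtrack import (
    BeamletFrame,
    SetupGeometry,
    extract_window,
    locate_grid,
    register_subpixel,
    render_beamlets,
    render_flat,
    sampling_pitch,
    stitch,
    to_refraction,
    track_frame,
    transmission,
    unstitch,
)
from beamtrack.tracking import TrackingMaps

from conftest import gaussian_spot


def _frame(intensity, origin=(20.0, 20.0), pitch=19.23, shape=(2, 2)):
    return BeamletFrame(
        intensity=intensity, grid_origin=origin, grid_pitch=pitch, grid_shape=shape
    )


class TestExtractWindow:
    def test_centred_patch(self):
        img = np.zeros((60, 60))
        img[20, 20] = 5.0
        frame = _frame(img)
        patch = extract_window(frame, (0, 0), 20)
        assert patch.shape == (20, 20)
        assert patch[10, 10] == 5.0  # beamlet centred

    def test_adjacent_windows_may_overlap(self):
        # 50/2.6 = 19.23 px pitch with 20 px windows: overlap is allowed,
        # each beamlet analysed independently
        img = np.random.default_rng(0).poisson(100, size=(80, 80)).astype(float)
        frame = _frame(img, shape=(1, 2))
        p0 = extract_window(frame, (0, 0), 20)
        p1 = extract_window(frame, (0, 1), 20)
        assert p0 is not None and p1 is not None
        # nominal centres 19.23 px apart -> 20 px windows share ~1 px
        assert np.array_equal(p0[:, -1], p1[:, 0])

    def test_edge_beamlet_flagged_missing(self):
        img = np.zeros((30, 30))
        frame = _frame(img, origin=(25.0, 15.0), shape=(1, 1))
        assert extract_window(frame, (0, 0), 20) is None


class TestTransmission:
    def test_identical_patches(self):
        p = np.full((8, 8), 3.0)
        assert transmission(p, p) == 1.0

    def test_half_transmission(self):
        p = np.full((8, 8), 3.0)
        assert transmission(0.5 * p, p) == pytest.approx(0.5, rel=1e-14)

    def test_sum_ratio(self):
        flat = np.full((10, 10), 90.0)  # sums 9.0e3
        sample = np.full((10, 10), 81.0)  # sums 8.1e3
        assert transmission(sample, flat) == pytest.approx(0.9, rel=1e-14)

    def test_zero_flat_invalid(self):
        assert math.isnan(transmission(np.ones((4, 4)), np.zeros((4, 4))))


class TestRegistration:
    def test_identical_patches(self):
        p = gaussian_spot(24, 11.5, 11.5)
        assert register_subpixel(p, p, 100) == (0.0, 0.0)

    def test_integer_shift_exact(self):
        flat = gaussian_spot(32, 15.0, 16.0)
        sample = np.roll(flat, (-2, 1), axis=(0, 1))  # moved +1 in x, -2 in y
        dx, dy = register_subpixel(sample, flat, 1)
        assert (dx, dy) == (1.0, -2.0)

    def test_subpixel_shift_vs_brute_force_scan(self):
        true = (0.30, -0.10)
        flat = gaussian_spot(24, 11.5, 11.5)
        sample = gaussian_spot(24, 11.5 + true[0], 11.5 + true[1])
        dx, dy = register_subpixel(sample, flat, 100)
        assert dx == pytest.approx(true[0], abs=0.01)
        assert dy == pytest.approx(true[1], abs=0.01)
        # independent brute-force correlation-peak scan at 0.001 px steps
        bx, by = _brute_force_shift(sample, flat)
        assert dx == pytest.approx(bx, abs=0.01)
        assert dy == pytest.approx(by, abs=0.01)

    def test_constant_patch_flagged(self):
        dx, dy = register_subpixel(np.ones((8, 8)), gaussian_spot(8, 4, 4), 10)
        assert math.isnan(dx) and math.isnan(dy)


def _brute_force_shift(sample, flat, step=0.001, rad=0.5):
    """Exhaustive correlation-peak scan, coarse 0.01 px then fine 0.001 px."""

    def corr(dx, dy):
        return float(np.sum(ndi.shift(flat, (dy, dx), order=3) * sample))

    best, bestv = (0.0, 0.0), -np.inf
    coarse = np.arange(-rad, rad + 1e-12, 0.01)
    for dx in coarse:
        for dy in coarse:
            v = corr(dx, dy)
            if v > bestv:
                bestv, best = v, (dx, dy)
    for dx in np.arange(best[0] - 0.01, best[0] + 0.01 + 1e-12, step):
        for dy in np.arange(best[1] - 0.01, best[1] + 0.01 + 1e-12, step):
            v = corr(dx, dy)
            if v > bestv:
                bestv, best = v, (dx, dy)
    return best


class TestToRefraction:
    def test_zero_displacement(self, small_geom):
        assert to_refraction(0.0, 0.0, small_geom) == (0.0, 0.0)

    def test_known_value(self, small_geom):
        # 0.01 px x 2.6 um / 1.28 m = 20.3 nrad
        ax, _ = to_refraction(0.01, 0.0, small_geom)
        assert ax == pytest.approx(2.03125e-8, rel=1e-12)

    def test_inverse_in_distance(self):
        g1 = SetupGeometry(z_od=1.0, mean_energy=16, pixel_size=2.6e-6,
                           modulator_period=50e-6, aperture_diameter=15e-6)
        g2 = SetupGeometry(z_od=2.0, mean_energy=16, pixel_size=2.6e-6,
                           modulator_period=50e-6, aperture_diameter=15e-6)
        assert to_refraction(0.5, 0.0, g1)[0] == pytest.approx(
            2 * to_refraction(0.5, 0.0, g2)[0], rel=1e-14
        )


class TestTrackFrame:
    def test_sample_equals_flat(self, small_geom):
        flat = render_flat((3, 4), small_geom, 1e4, seed=None)
        maps = track_frame(flat, flat, 100.0, small_geom, window=16)
        np.testing.assert_allclose(maps.t, 1.0, atol=1e-12)
        np.testing.assert_allclose(maps.dx, 0.0, atol=0.01)
        np.testing.assert_allclose(maps.dy, 0.0, atol=0.01)

    def test_dead_beamlet_masked(self, small_geom):
        flat = render_flat((3, 3), small_geom, 1e4, seed=None, dark_level=0.0)
        sample = render_flat((3, 3), small_geom, 1e4, seed=None, dark_level=0.0)
        cx, cy = sample.beamlet_center(1, 1)
        sample.intensity[int(cy) - 9 : int(cy) + 9, int(cx) - 9 : int(cx) + 9] = 0.0
        maps = track_frame(sample, flat, None, small_geom, window=16)
        assert maps.mask.sum() == 1
        assert maps.mask[1, 1]

    def test_mismatched_grids_rejected(self, small_geom):
        f1 = render_flat((2, 2), small_geom, 1e3, seed=None)
        f2 = render_flat((2, 3), small_geom, 1e3, seed=None)
        with pytest.raises(ValueError, match="grid"):
            track_frame(f1, f2, None, small_geom)

    def test_linearity_of_recovered_angle(self, small_geom):
        # imposed refraction vs recovered: slope 1 +/- 2% over +/- 5 urad
        k = small_geom.wavenumber
        alphas = np.linspace(-5e-6, 5e-6, 9)
        recovered = []
        flat = render_flat((3, 3), small_geom, 1e4, seed=None)
        for a in alphas:
            fr = render_beamlets(
                np.ones((3, 3)), np.full((3, 3), a * k), np.zeros((3, 3)),
                small_geom, 1e4, seed=None,
            )
            maps = track_frame(fr, flat, 100.0, small_geom, window=16)
            recovered.append(np.nanmean(maps.alpha_x))
        slope = np.polyfit(alphas, recovered, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)


def _const_maps(value, a, b, shape=(2, 2)):
    arr = np.full(shape, float(value))
    return TrackingMaps(t=arr, dx=arr * 0, dy=arr * 0, alpha_x=arr.copy(),
                        alpha_y=arr.copy(), raster_index=(a, b))


class TestStitch:
    def test_identity_for_single_position(self):
        m = _const_maps(7.0, 0, 0)
        out = stitch([m], 1)
        np.testing.assert_array_equal(out.t, m.t)

    def test_interleave_order(self):
        # output pixel (i*n+b, j*n+a) <- offset (a, b); +x offset fills +x
        maps = [_const_maps(1 + a + 2 * b, a, b, shape=(1, 1)) for a in range(2) for b in range(2)]
        out = stitch(maps, 2)
        np.testing.assert_array_equal(out.t, [[1.0, 2.0], [3.0, 4.0]])

    def test_duplicate_offsets_rejected(self):
        maps = [_const_maps(1, 0, 0), _const_maps(2, 0, 0),
                _const_maps(3, 1, 0), _const_maps(4, 1, 1)]
        with pytest.raises(ValueError, match="lattice"):
            stitch(maps, 2)

    def test_stitch_unstitch_roundtrip(self):
        rng = np.random.default_rng(7)
        n = 3
        maps = [
            TrackingMaps(
                t=rng.normal(size=(4, 5)), dx=np.zeros((4, 5)), dy=np.zeros((4, 5)),
                alpha_x=rng.normal(size=(4, 5)), alpha_y=rng.normal(size=(4, 5)),
                raster_index=(a, b),
            )
            for a in range(n)
            for b in range(n)
        ]
        out = stitch(maps, n)
        parts = unstitch(out.t, n)
        for m in maps:
            np.testing.assert_array_equal(parts[m.raster_index], m.t)

    def test_stitched_map_matches_ground_truth(self, noiseless_scan, small_geom):
        n = small_geom.n_subpitch
        maps = [
            track_frame(noiseless_scan.frames[(0, a, b)], noiseless_scan.flats[(a, b)],
                        noiseless_scan.dark, small_geom, window=16)
            for a in range(n)
            for b in range(n)
        ]
        proj = stitch(maps, n, angle=0.0, pitch=sampling_pitch(small_geom))
        truth = noiseless_scan.truth[0]
        assert np.sqrt(np.nanmean((proj.t - truth.t) ** 2)) < 2e-3
        alpha_truth = truth.gradx / small_geom.wavenumber
        # registration quantum: 0.01 px -> ~20 nrad at 1.28 m
        assert np.nanmax(np.abs(proj.alpha_x - alpha_truth)) < 3e-8


def test_locate_grid_on_flat(small_geom):
    flat = render_flat((6, 6), small_geom, 1e4, seed=None, dark_level=0.0)
    (x0, y0), pitch = locate_grid(flat.intensity, approx_pitch=small_geom.grid_pitch_px)
    assert pitch == pytest.approx(small_geom.grid_pitch_px, abs=0.15)
    assert x0 == pytest.approx(flat.grid_origin[0], abs=0.5)
    assert y0 == pytest.approx(flat.grid_origin[1], abs=0.5)
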