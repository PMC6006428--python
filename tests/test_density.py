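"""Volumetric core: I/O round trips, Fourier filters, symmetry, FSC."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcfit.density import (
    DensityMap,
    MapFormatError,
    Pose,
    WedgeDescriptor,
    apply_wedge,
    centered_map,
    fsc,
    lowpass_filter,
    read_map,
    resolution_at,
    rotate_about_axis,
    symmetrize,
    transform_map,
    wedge_mask,
    write_map,
)
from npcfit.phantoms import make_subunit, render_density


def _corr(a, b):
    a, b = a.ravel() - a.mean(), b.ravel() - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


class TestMapIO:
    def test_round_trip_identity(self, tmp_path, rng):
        m = centered_map(rng.normal(size=(16, 16, 16)).astype(np.float32), 2.0)
        write_map(m, tmp_path / "m.mrc")
        r = read_map(tmp_path / "m.mrc")
        np.testing.assert_array_equal(r.values, m.values)
        assert r.voxel_size == pytest.approx(m.voxel_size)
        np.testing.assert_allclose(r.origin, m.origin, atol=1e-5)

    def test_header_metadata_against_independent_parser(self, tmp_path, rng):
        m = DensityMap(rng.normal(size=(32, 32, 32)).astype(np.float32), 1.5,
                       origin=np.array([-24.0, -24.0, -24.0]))
        path = tmp_path / "m.mrc"
        write_map(m, path)
        raw = path.read_bytes()
        nx, ny, nz = struct.unpack_from("<3i", raw, 0)
        cella = struct.unpack_from("<3f", raw, 40)
        origin = struct.unpack_from("<3f", raw, 196)
        assert (nx, ny, nz) == (32, 32, 32)
        # header lengths are in Angstrom
        assert cella[0] / nx == pytest.approx(15.0)
        assert origin == pytest.approx((-240.0, -240.0, -240.0))

    def test_zero_voxel_size_rejected(self):
        with pytest.raises(ValueError, match="voxel_size"):
            DensityMap(np.zeros((4, 4, 4)), voxel_size=0.0)

    def test_anisotropic_voxel_rejected(self, tmp_path):
        import gemmi

        g = gemmi.Ccp4Map()
        g.grid = gemmi.FloatGrid(np.zeros((8, 8, 8), dtype=np.float32))
        g.grid.unit_cell = gemmi.UnitCell(80, 80, 160, 90, 90, 90)
        g.update_ccp4_header()
        g.write_ccp4_map(str(tmp_path / "aniso.mrc"))
        with pytest.raises(MapFormatError, match="anisotropic"):
            read_map(tmp_path / "aniso.mrc")


class TestLowpass:
    def test_constant_map_unchanged(self):
        m = centered_map(np.full((16, 16, 16), 3.5), 2.0)
        out = lowpass_filter(m, 8.0)
        np.testing.assert_allclose(out.values, m.values, atol=1e-10)

    def test_idempotent_within_tolerance(self, random_map16):
        once = lowpass_filter(random_map16, 8.0)
        twice = lowpass_filter(once, 8.0)
        # the raised-cosine edge spans one frequency shell, so a second pass
        # only re-attenuates that single shell
        rms = np.sqrt(np.mean((twice.values - once.values) ** 2))
        assert rms < 0.15 * np.std(once.values)

    def test_power_beyond_cutoff_removed(self, rng):
        m = centered_map(rng.normal(size=(32, 32, 32)), 1.0)
        out = lowpass_filter(m, 6.0)
        # independent spectrum oracle
        F = np.fft.fftn(out.values)
        k = np.meshgrid(*(np.fft.fftfreq(32, d=1.0),) * 3, indexing="ij")
        f = np.sqrt(sum(x**2 for x in k))
        beyond = float(np.sum(np.abs(F[f > 1.0 / 6.0]) ** 2))
        total = float(np.sum(np.abs(F) ** 2))
        assert beyond / total < 1e-3

    def test_mean_preserved(self, random_map16):
        out = lowpass_filter(random_map16, 10.0)
        assert out.values.mean() == pytest.approx(random_map16.values.mean(), abs=1e-10)

    def test_cutoff_below_nyquist_rejected(self, random_map16):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(random_map16, 1.0)


class TestSymmetrize:
    def test_order_one_is_identity(self, random_map16):
        out = symmetrize(random_map16, 1)
        np.testing.assert_array_equal(out.values, random_map16.values)

    def test_c8_output_rotationally_invariant(self, smooth_phantom):
        sym = symmetrize(smooth_phantom, 8)
        rot = rotate_about_axis(sym, 45.0)
        assert _corr(sym.values, rot.values) >= 0.999

    def test_symmetric_phantom_nearly_unchanged(self):
        # analytic C8-symmetric phantom: ring of 8 identical gaussians
        from npcfit.phantoms import ArchitectureSpec, RingSpec, build_assembly

        spec = ArchitectureSpec(8, [RingSpec("rod", 8, 12.0, 0.0, ring_id="r")])
        _, merged = build_assembly(spec, {"rod": make_subunit("rod", {"length_nm": 0.1})})
        m = render_density(merged, 1.5, 48.0, 8.0)
        out = symmetrize(m, 8)
        rms = np.sqrt(np.mean((out.values - m.values) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(m.values**2))

    def test_projection_idempotence(self, smooth_phantom):
        s1 = symmetrize(smooth_phantom, 4)
        s2 = symmetrize(s1, 4)
        assert _corr(s1.values, s2.values) > 0.9999

    def test_invalid_order(self, random_map16):
        with pytest.raises(ValueError):
            symmetrize(random_map16, 0)


class TestTransform:
    def test_identity_exact(self, random_map16):
        out = transform_map(random_map16, Pose.identity())
        np.testing.assert_array_equal(out.values, random_map16.values)

    def test_axis_rotation_matches_grid_permutation(self, rng):
        m = centered_map(rng.normal(size=(9, 9, 9)), 1.0)
        out = transform_map(m, Pose((90.0, 0.0, 0.0)))
        # rotating the object by +90 deg about z maps axis x onto y
        expected = np.rot90(m.values, k=1, axes=(0, 1))
        np.testing.assert_allclose(out.values, expected, atol=1e-8)

    def test_transform_inverse_round_trip(self, smooth_phantom):
        pose = Pose((25.0, 10.0, -40.0), (2.0, -1.5, 3.0))
        back = transform_map(transform_map(smooth_phantom, pose), pose.inverse())
        assert _corr(back.values, smooth_phantom.values) >= 0.99

    def test_grid_shape_and_voxel_preserved(self, smooth_phantom):
        out = transform_map(smooth_phantom, Pose((10, 20, 30), (1, 2, 3)))
        assert out.shape == smooth_phantom.shape
        assert out.voxel_size == smooth_phantom.voxel_size


class TestPose:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-180, 180), min_size=3, max_size=3),
           st.lists(st.floats(-20, 20), min_size=3, max_size=3))
    def test_compose_with_inverse_is_identity(self, euler, trans):
        p = Pose(tuple(euler), tuple(trans))
        r = p.compose(p.inverse())
        assert r.rotation_angle_deg() < 1e-6
        np.testing.assert_allclose(r.t, 0.0, atol=1e-9)


class TestWedge:
    def test_full_range_is_noop(self, random_map16):
        out = apply_wedge(random_map16, WedgeDescriptor(-90, 90))
        np.testing.assert_allclose(out.values, random_map16.values, atol=1e-10)

    def test_missing_fraction_matches_analytic(self):
        # count zeroed voxels inside the Nyquist sphere, where the angular
        # measure of the wedge (1/3 for a +/-60 degree tilt range) applies
        w = WedgeDescriptor(-60, 60)
        n = 48
        mask = wedge_mask((n, n, n), w)
        k = np.meshgrid(*(np.fft.fftfreq(n),) * 3, indexing="ij")
        sphere = np.sqrt(sum(x**2 for x in k)) <= 0.5
        measured = 1.0 - mask[sphere].mean()
        assert measured == pytest.approx(w.missing_fraction(), abs=0.02)

    def test_projection_idempotent(self, random_map16):
        w = WedgeDescriptor(-60, 60)
        once = apply_wedge(random_map16, w)
        twice = apply_wedge(once, w)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_commutes_with_lowpass(self, random_map16):
        w = WedgeDescriptor(-60, 60)
        a = lowpass_filter(apply_wedge(random_map16, w), 8.0)
        b = apply_wedge(lowpass_filter(random_map16, 8.0), w)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            WedgeDescriptor(60, -60)


class TestFSC:
    def test_self_correlation_is_one(self, smooth_phantom):
        freq, curve = fsc(smooth_phantom, smooth_phantom)
        np.testing.assert_allclose(curve, 1.0, atol=1e-9)

    def test_independent_noise_within_sampling_bound(self, rng):
        n = 32
        a = centered_map(rng.normal(size=(n, n, n)), 1.0)
        b = centered_map(rng.normal(size=(n, n, n)), 1.0)
        freq, curve = fsc(a, b)
        # voxel counts per shell for the sampling-error bound
        idx = [np.fft.fftfreq(n) * n for n in a.shape]
        kx, ky, kz = np.meshgrid(*idx, indexing="ij")
        shell = np.rint(np.sqrt(kx**2 + ky**2 + kz**2)).astype(int)
        for s in range(2, n // 2):
            count = int(np.sum(shell == s))
            assert abs(curve[s]) < 3.0 / np.sqrt(count)

    def test_half_set_resolution_tracks_rendering_resolution(self):
        model = make_subunit("blob-cluster", {"n_beads": 30, "extent_nm": 12.0}, seed=3)
        m = render_density(model, 1.5, 48.0, 4.0)
        g = np.random.default_rng(0)
        sd = m.values.std()
        a = m.with_values(m.values + g.normal(0, sd / np.sqrt(2.0), m.shape))
        b = m.with_values(m.values + g.normal(0, sd / np.sqrt(2.0), m.shape))
        res = resolution_at(fsc(a, b), 0.143)
        step = 1.0 / (min(m.shape) * m.voxel_size)
        assert abs(1.0 / res - 1.0 / 4.0) <= step

    def test_mismatched_grids_rejected(self, smooth_phantom, random_map16):
        with pytest.raises(ValueError):
            fsc(smooth_phantom, random_map16)
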