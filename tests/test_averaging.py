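"""Constrained cross-correlation, alignment and wedge-weighted averaging."""

import numpy as np
import pytest

from npcfit.averaging import (
    align_particle,
    constrained_cc,
    extract_asymmetric_units,
    iterative_average,
    masked_refine,
    wedge_weighted_average,
)
from npcfit.density import (
    Pose,
    WedgeDescriptor,
    apply_wedge,
    fsc,
    resolution_at,
    rotate_about_axis,
    symmetrize,
    wedge_mask,
)
from npcfit.phantoms import (
    ArchitectureSpec,
    RingSpec,
    Subtomogram,
    build_assembly,
    generate_particle_set,
    make_subunit,
    render_density,
    simulate_particle,
)

WEDGE = WedgeDescriptor(-60, 60)


@pytest.fixture(scope="module")
def ring_map():
    """Small C4 ring of chiral Y subunits: 32^3 at 3 nm voxels."""
    spec = ArchitectureSpec(4, [RingSpec("Y", 4, 24.0, 0.0, ring_id="r")])
    _, merged = build_assembly(spec, {"Y": make_subunit("Y", {"stem_nm": 18, "arm_nm": 10})})
    return render_density(merged, 3.0, 96.0, 7.0)


@pytest.fixture(scope="module")
def reference(ring_map):
    return symmetrize(ring_map, 4)


class TestConstrainedCC:
    def test_identical_volumes_score_one(self, ring_map):
        wedged = apply_wedge(ring_map, WEDGE)
        assert constrained_cc(wedged, wedged, WEDGE, WEDGE) == pytest.approx(1.0, abs=1e-6)

    def test_shifted_volume_scores_lower(self, ring_map):
        wedged = apply_wedge(ring_map, WEDGE)
        shifted = wedged.with_values(np.roll(wedged.values, 5, axis=0))
        full = constrained_cc(wedged, wedged, WEDGE, WEDGE)
        off = constrained_cc(shifted, wedged, WEDGE, WEDGE)
        assert off < full

    def test_matches_explicit_masked_sum_oracle(self, ring_map, rng):
        noisy = ring_map.with_values(
            ring_map.values + rng.normal(0, ring_map.values.std(), ring_map.shape)
        )
        volume = apply_wedge(noisy, WEDGE)
        score = constrained_cc(volume, ring_map, WEDGE, None)
        # brute-force oracle: explicit sums over the volume's wedge region
        mask = wedge_mask(ring_map.shape, WEDGE)
        mask = mask.copy()
        mask.flat[0] = False
        A = np.fft.fftn(volume.values)[mask]
        B = np.fft.fftn(ring_map.values)[mask]
        expected = np.real(np.sum(A * np.conj(B))) / np.sqrt(
            np.sum(np.abs(A) ** 2) * np.sum(np.abs(B) ** 2)
        )
        assert score == pytest.approx(expected, abs=1e-5)

    def test_disjoint_wedges_rejected(self, ring_map):
        with pytest.raises(ValueError, match="coverage"):
            constrained_cc(ring_map, ring_map, WedgeDescriptor(-80, -70),
                           WedgeDescriptor(70, 80))


class TestAlignment:
    def test_particle_equal_to_reference_gives_identity(self, reference):
        p = Subtomogram(reference.copy(), WedgeDescriptor(-90, 89.99), Pose(), None)
        pose, _ = align_particle(p, reference, angular_step=15.0, max_shift_nm=6.0)
        assert pose.rotation_angle_deg() < 1e-6
        np.testing.assert_allclose(pose.t, 0.0, atol=1e-9)

    def test_planted_rotation_recovered_noise_free(self, ring_map, reference):
        planted = Pose((30.0, 0.0, 0.0), (3.0, 0.0, 0.0))
        p = simulate_particle(ring_map, WEDGE, None, seed=0, pose=planted)
        pose, _ = align_particle(p, reference, angular_step=10.0, max_shift_nm=9.0)
        dphi = (pose.euler_deg[0] + pose.euler_deg[2] - 30.0) % 90.0  # C4 reference
        assert min(dphi, 90 - dphi) <= 10.0
        assert np.linalg.norm(pose.t - planted.t) <= 2 * ring_map.voxel_size

    def test_inplane_recovery_rate_at_moderate_noise(self, ring_map, reference):
        # >=90% of in-plane angles within one angular step at snr >= 1
        n_ok, n = 0, 16
        particles, truth = generate_particle_set(ring_map, n, WEDGE, 1.0, seed=5)
        for p in particles:
            pose, _ = align_particle(p, reference, angular_step=10.0, max_shift_nm=9.0)
            true_phi = p.true_pose.euler_deg[0] + p.true_pose.euler_deg[2]
            est_phi = pose.euler_deg[0] + pose.euler_deg[2]
            d = (est_phi - true_phi) % 90.0
            n_ok += min(d, 90 - d) <= 10.0
        assert n_ok >= 0.9 * n


class TestAveraging:
    def test_identical_noise_free_particles_average_to_particle(self, ring_map):
        wedged = apply_wedge(ring_map, WEDGE)
        parts = [Subtomogram(wedged.copy(), WEDGE, Pose(), None) for _ in range(4)]
        avg = wedge_weighted_average(parts)
        rms = np.sqrt(np.mean((avg.values - wedged.values) ** 2))
        assert rms < 1e-6 * np.sqrt(np.mean(wedged.values**2)) + 1e-12

    def test_average_independent_of_particle_count(self, ring_map):
        wedged = apply_wedge(ring_map, WEDGE)
        a = wedge_weighted_average([Subtomogram(wedged.copy(), WEDGE, Pose(), None)] * 2)
        b = wedge_weighted_average([Subtomogram(wedged.copy(), WEDGE, Pose(), None)] * 6)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_more_particles_never_worse_resolution(self, ring_map, reference):
        # the reference seeds the alignment, as the manual pre-orientation
        # step does for real data
        def avg_of(n, seed):
            parts, _ = generate_particle_set(ring_map, n, WEDGE, 0.5, seed=seed)
            out, _ = iterative_average(parts, initial_reference=reference,
                                       n_iter=1, symmetry_order=4,
                                       angular_step=15.0, max_shift_nm=6.0)
            return out

        res_small = resolution_at(fsc(avg_of(4, 1), avg_of(4, 2)), 0.143)
        res_large = resolution_at(fsc(avg_of(16, 3), avg_of(16, 4)), 0.143)
        assert res_large <= res_small + 1e-9

    def test_symmetry_imposed_on_final_average(self, ring_map):
        parts, _ = generate_particle_set(ring_map, 4, WEDGE, 1.0, seed=9)
        avg, state = iterative_average(parts, n_iter=1, symmetry_order=4,
                                       angular_step=15.0, max_shift_nm=6.0)
        rot = rotate_about_axis(avg, 90.0)
        a, b = avg.values.ravel() - avg.values.mean(), rot.values.ravel() - rot.values.mean()
        assert a @ b / np.sqrt((a @ a) * (b @ b)) >= 0.999


class TestAsymmetricUnits:
    def test_one_particle_yields_order_units(self, reference):
        p = Subtomogram(reference.copy(), WEDGE, Pose(), None)
        units = extract_asymmetric_units([p], [Pose()], 4, unit_box=12,
                                         unit_center_nm=(24.0, 0.0, 0.0))
        assert len(units) == 4

    def test_units_of_symmetric_phantom_are_equivalent(self):
        # odd grid (33^3) keeps the symmetry axis on-lattice, so the four
        # units are related by exact lattice rotations
        spec = ArchitectureSpec(4, [RingSpec("Y", 4, 24.0, 0.0, ring_id="r")])
        _, merged = build_assembly(
            spec, {"Y": make_subunit("Y", {"stem_nm": 18, "arm_nm": 10})}
        )
        ref = symmetrize(render_density(merged, 3.0, 99.0, 7.0), 4)
        full = WedgeDescriptor(-90, 90)
        p = Subtomogram(apply_wedge(ref, full), full, Pose(), None)
        units = extract_asymmetric_units([p], [Pose()], 4, unit_box=12,
                                         unit_center_nm=(24.0, 0.0, 0.0))
        vals = [u.map.values.ravel() for u in units]
        for v in vals[1:]:
            a, b = vals[0] - vals[0].mean(), v - v.mean()
            assert a @ b / np.sqrt((a @ a) * (b @ b)) >= 0.99

    def test_oversized_unit_box_rejected(self, reference):
        p = Subtomogram(reference.copy(), WEDGE, Pose(), None)
        with pytest.raises(ValueError, match="exceeds"):
            extract_asymmetric_units([p], [Pose()], 4, unit_box=64)


class TestMaskedRefine:
    def test_all_ones_mask_equals_unmasked_refinement(self, reference):
        parts, _ = generate_particle_set(reference, 3, WEDGE, 2.0, seed=4)
        ones = np.ones(reference.shape)
        out = masked_refine(parts, {"all": ones}, reference=reference,
                            angular_step=10.0, max_shift_nm=3.0)
        # unmasked refinement done by hand
        poses = [align_particle(u, reference, 10.0, 3.0)[0] for u in parts]
        expected = wedge_weighted_average(parts, poses)
        np.testing.assert_allclose(out["all"].values, expected.values, atol=1e-9)

    def test_disjoint_masks_change_only_their_support(self, reference):
        parts, _ = generate_particle_set(reference, 3, WEDGE, 2.0, seed=4)
        n = reference.shape[2]
        top = np.zeros(reference.shape)
        top[:, :, n // 2:] = 1.0
        bottom = 1.0 - top
        out = masked_refine(parts, {"top": top, "bottom": bottom},
                            reference=reference, angular_step=10.0, max_shift_nm=3.0)
        raw = wedge_weighted_average(parts)
        np.testing.assert_allclose(out["top"].values[bottom > 0],
                                   raw.values[bottom > 0], atol=1e-9)
        np.testing.assert_allclose(out["bottom"].values[top > 0],
                                   raw.values[top > 0], atol=1e-9)

    def test_empty_mask_rejected(self, reference):
        parts, _ = generate_particle_set(reference, 2, WEDGE, 2.0, seed=4)
        with pytest.raises(ValueError, match="empty"):
            masked_refine(parts, {"void": np.zeros(reference.shape)})
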