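"""Systematic fitting: scoring, exhaustive search, significance, clustering."""

import numpy as np
import pandas as pd
import pytest

from npcfit.density import Pose, centered_map
from npcfit.fitting import (
    RigidFit,
    assess_significance,
    cluster_fits,
    count_copies,
    envelope_threshold,
    exhaustive_search,
    hierarchical_fit,
    score_fit,
    so3_grid,
    so3_grid_size,
)
from npcfit.phantoms import (
    ArchitectureSpec,
    RingSpec,
    build_assembly,
    make_subunit,
    render_density,
)


@pytest.fixture(scope="module")
def y_model_map():
    return render_density(make_subunit("Y", {"stem_nm": 14, "arm_nm": 8}), 3.0, 96.0, 7.0)


@pytest.fixture(scope="module")
def planted_y(y_model_map):
    """A single Y planted at a known pose inside an otherwise empty box."""
    pose = Pose((40.0, 0.0, 0.0), (9.0, -6.0, 3.0))
    from npcfit.density import transform_map

    return transform_map(y_model_map, pose), pose


class TestScoreFit:
    def test_self_fit_at_truth_is_perfect(self, y_model_map):
        cc, ov, score = score_fit(y_model_map, y_model_map, Pose())
        assert cc >= 0.999 and ov >= 0.999

    def test_disjoint_placement_scores_zero(self, y_model_map, planted_y):
        target, _ = planted_y
        cc, ov, score = score_fit(y_model_map, target, Pose((0, 0, 0), (-30.0, 30.0, -20.0)))
        assert ov <= 0.05
        assert abs(score) <= 0.05

    def test_truth_pose_beats_random_poses(self, crnpc_assembly):
        _, subunits, truth, _, amap = crnpc_assembly
        ymap = render_density(subunits["Y-complex"], 3.0, 132.0, 6.0)
        row = truth[truth.ring == "CR"].iloc[0]
        truth_pose = Pose((row.alpha, row.beta, row.gamma), (row.tx, row.ty, row.tz))
        thr = (envelope_threshold(ymap.values), envelope_threshold(amap.values))
        truth_score = score_fit(ymap, amap, truth_pose, thr)[2]
        rng = np.random.default_rng(0)
        scores = []
        for _ in range(1000):
            pose = Pose(tuple(rng.uniform(0, 360, 3)), tuple(rng.uniform(-45, 45, 3)))
            scores.append(score_fit(ymap, amap, pose, thr)[2])
        assert truth_score > np.percentile(scores, 95)

    def test_invariants_of_fit_record(self):
        with pytest.raises(ValueError):
            RigidFit(Pose(), cc=1.5, overlap=0.5, score=0.75)
        with pytest.raises(ValueError):
            RigidFit(Pose(), cc=0.5, overlap=1.5, score=0.75)


class TestOrientationGrid:
    @pytest.mark.parametrize("step", [20.0, 30.0, 45.0])
    def test_grid_size_matches_independent_count(self, step):
        # independent recount of the quasi-uniform construction
        n_dirs = round(4 * np.pi / np.radians(step) ** 2)
        n_inplane = round(360.0 / step)
        assert so3_grid_size(step) == (n_dirs, n_inplane)
        assert len(so3_grid(step)) == n_dirs * n_inplane

    def test_invalid_step(self):
        with pytest.raises(ValueError):
            so3_grid(0.0)


class TestExhaustiveSearch:
    def test_accelerated_scan_equals_direct_scoring(self, rng):
        """FFT translational scan vs per-pose direct evaluation on 16^3."""
        model_vals = np.zeros((16, 16, 16))
        model_vals[6:10, 6:10, 7:9] = rng.random((4, 4, 2)) + 0.5
        model = centered_map(model_vals, 2.0)
        target = centered_map(rng.random((16, 16, 16)), 2.0)
        thr_m = envelope_threshold(model.values)
        thr_t = envelope_threshold(target.values)
        ens = exhaustive_search(model, target, angular_step=60.0,
                                model_threshold=thr_m, target_threshold=thr_t)
        sx, sy, sz = ens.lattice_shifts
        checked = 0
        for o in [0, len(ens.rotations) // 2]:
            for idx in [(0, 0, 0), (2, 3, 1), (13, 14, 15), (5, 0, 12)]:
                # stay clear of wrap-around: interior shifts only
                if max(abs(sx[idx[0]]), abs(sy[idx[1]]), abs(sz[idx[2]])) > 4:
                    continue
                pose = ens.pose_at(o, idx)
                cc, ov, _ = score_fit(model, target, pose, (thr_m, thr_t))
                assert ens.cc[o][idx] == pytest.approx(cc, abs=1e-5)
                assert ens.overlap[o][idx] == pytest.approx(ov, abs=1e-5)
                checked += 1
        assert checked >= 4

    def test_planted_model_recovered_within_one_grid_step(self, planted_y, y_model_map):
        target, pose = planted_y
        ens = exhaustive_search(y_model_map, target, angular_step=20.0)
        best = ens.best()
        from npcfit.density import rotation_distance_deg

        d_rot = rotation_distance_deg(best.pose.matrix, pose.matrix)
        d_t = np.linalg.norm(best.pose.t - pose.t)
        assert d_rot <= 20.0
        assert d_t <= np.sqrt(3) * target.voxel_size + 1e-9

    def test_all_zero_map_is_handled(self, y_model_map):
        target = y_model_map.with_values(np.zeros(y_model_map.shape))
        ens = exhaustive_search(y_model_map, target, angular_step=60.0)
        assert np.all(ens.cc == 0.0)
        assert np.all(ens.overlap == 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            assess_significance(ens)


class TestSignificance:
    def test_p_monotone_nonincreasing_in_score(self, planted_y, y_model_map):
        target, _ = planted_y
        noisy = target.with_values(
            target.values
            + np.random.default_rng(3).normal(0, 0.3 * target.values.std(), target.shape)
        )
        ens = exhaustive_search(y_model_map, noisy, angular_step=40.0)
        assess_significance(ens)
        df = ens.significance.maxima.sort_values("score")
        assert (np.diff(df["p"].to_numpy()) <= 1e-12).all()

    def test_null_calibration_on_pure_noise(self, y_model_map):
        """Significant local-maxima fraction stays below alpha on noise."""
        small_model = render_density(
            make_subunit("rod", {"length_nm": 8.0}), 2.0, 32.0, 5.0
        )
        fracs = []
        for seed in range(20):
            noise = centered_map(
                np.random.default_rng(seed).normal(size=(16, 16, 16)), 2.0
            )
            thr_t = envelope_threshold(noise.values)
            ens = exhaustive_search(small_model, noise, angular_step=40.0,
                                    target_threshold=thr_t)
            assess_significance(ens, alpha=0.05)
            m = ens.significance.maxima
            fracs.append(m["significant"].mean() if len(m) else 0.0)
        assert np.mean(fracs) <= 0.05


class TestClustering:
    def test_single_planted_copy_gives_single_placement(self, planted_y, y_model_map):
        from npcfit.fitting import accept_placements

        target, pose = planted_y
        ens = exhaustive_search(y_model_map, target, angular_step=24.0)
        assess_significance(ens)
        cl = cluster_fits(ens, trans_tol=8.0)
        acc, _ = accept_placements(ens, cl, y_model_map, target,
                                   min_separation_nm=12.0,
                                   relative_overlap_floor=0.75)
        assert len(acc) == 1
        assert np.linalg.norm(acc.iloc[0][["tx", "ty", "tz"]].to_numpy(float) - pose.t) <= 6.0

    def test_c8_ring_clusters_are_45_degrees_apart(self, crnpc_assembly):
        _, subunits, truth, _, amap = crnpc_assembly
        from npcfit.architecture import ring_region_masks
        from npcfit.experiments import Y_ACCEPT
        from npcfit.fitting import significant_placements

        masks = ring_region_masks(amap, 17.0)
        ring = amap.with_values(amap.values * (masks["CR"].values > 0))
        ring.meta["resolution_nm"] = 6.0
        acc = significant_placements(subunits["Y-complex"], ring, angular_step=24.0,
                                     resolution_nm=6.0, **Y_ACCEPT)
        assert len(acc) == 8
        az = np.degrees(np.arctan2(acc["ty"], acc["tx"])) % 360.0
        az = np.sort(az)
        gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
        np.testing.assert_allclose(gaps, 45.0, atol=10.0)

    def test_duplicate_candidates_cluster_identically(self, planted_y, y_model_map):
        target, _ = planted_y
        ens = exhaustive_search(y_model_map, target, angular_step=40.0)
        assess_significance(ens)
        base = ens.significance.maxima
        doubled = pd.concat([base, base], ignore_index=True).sort_values(
            "score", ascending=False, ignore_index=True
        )
        a = cluster_fits(ens, trans_tol=8.0)
        b = cluster_fits(ens, trans_tol=8.0, candidates=doubled)
        pd.testing.assert_frame_equal(
            a[["tx", "ty", "tz", "score"]], b[["tx", "ty", "tz", "score"]]
        )

    def test_invalid_tolerances(self, planted_y, y_model_map):
        target, _ = planted_y
        ens = exhaustive_search(y_model_map, target, angular_step=60.0)
        with pytest.raises(ValueError):
            cluster_fits(ens, rot_tol=-1.0, trans_tol=5.0)


class TestHierarchicalFit:
    def test_two_subunit_phantom_assigned_in_order_with_empty_residual(self):
        rod = make_subunit("rod", {"length_nm": 16.0})
        blob = make_subunit("blob-cluster", {"n_beads": 6, "extent_nm": 5.0}, seed=3)
        spec = ArchitectureSpec(4, [
            RingSpec("rod", 4, 26.0, 14.0, ring_id="big"),
            RingSpec("blob-cluster", 4, 20.0, -14.0, ring_id="small"),
        ])
        truth, merged = build_assembly(spec, {"rod": rod, "blob-cluster": blob})
        target = render_density(merged, 2.5, 90.0, 5.0)
        target.meta["resolution_nm"] = 5.0
        assignment, residual = hierarchical_fit(
            target, [("rod", rod), ("blob-cluster", blob)],
            angular_step=30.0, trans_tol=10.0, resolution_nm=5.0,
            relative_overlap_floor=0.7, subtract=True,
        )
        assert list(assignment["model"].unique()) == ["rod", "blob-cluster"]
        from scipy.spatial.distance import cdist

        for label in ("rod", "blob-cluster"):
            placed = assignment[assignment.model == label]
            planted = truth[truth.subunit == label][["tx", "ty", "tz"]].to_numpy()
            assert len(placed) == 4
            d = cdist(placed[["tx", "ty", "tz"]], planted).min(axis=1)
            assert (d <= 6.0).all()
        # after all copies are accepted and subtracted, re-searching the
        # residual finds nothing
        residual.meta["resolution_nm"] = 5.0
        again, _ = hierarchical_fit(residual, [("rod", rod)], angular_step=30.0,
                                    trans_tol=10.0, resolution_nm=5.0,
                                    relative_overlap_floor=0.7)
        assert again.empty

    def test_empty_model_list_leaves_map_unchanged(self, planted_y):
        target, _ = planted_y
        assignment, residual = hierarchical_fit(target, [])
        assert assignment.empty
        np.testing.assert_array_equal(residual.values, target.values)


class TestCountCopies:
    def test_empty_assignment_counts_zero(self, crnpc_assembly):
        from npcfit.architecture import ring_region_masks
        from npcfit.fitting import FIT_COLUMNS

        _, _, _, _, amap = crnpc_assembly
        masks = ring_region_masks(amap)
        counts = count_copies(pd.DataFrame(columns=["model", *FIT_COLUMNS]), masks)
        assert counts.to_numpy().sum() == 0

    def test_placements_attributed_by_region(self, crnpc_assembly):
        from npcfit.architecture import ring_region_masks

        _, _, truth, _, amap = crnpc_assembly
        masks = ring_region_masks(amap, 17.0)
        table = truth.rename(columns={"subunit": "model"})
        counts = count_copies(table, masks)
        assert counts.loc["Y-complex", "CR"] == 8
        assert counts.loc["Y-complex", "NR"] == 16
        assert counts.loc["IR-protomer", "IR"] == 32
        assert counts["unassigned"].sum() == 0
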