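"""PAM pose clustering, silhouette k selection, and region occupancies."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import pam_exhaustive

from pepsurf.pose_regions import (
    OTHER_REGION,
    PoseLocalization,
    RegionDefinition,
    ResidueKey,
    assign_regions,
    choose_k,
    load_regions,
    localize_poses,
    pam_cluster,
    save_regions,
)
from pepsurf.structure_io import center_of_mass
from pepsurf.synthetic_data import (
    FAR_POINT,
    gen_pose_ensemble,
    gen_receptor,
    peptide_ca_template,
    region_anchor,
)


def blobs(rng, centers, n_per, spread=0.5):
    pts = np.concatenate(
        [c + rng.normal(scale=spread, size=(n_per, 3)) for c in np.asarray(centers, float)]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


class TestPAM:
    def test_k_equals_n_zero_cost(self, rng):
        pts = rng.normal(size=(6, 3))
        medoids, labels, cost = pam_cluster(pts, k=6)
        assert sorted(medoids) == list(range(6))
        assert cost == 0.0

    def test_attains_exhaustive_optimum_small(self, rng):
        for trial in range(10):
            pts = rng.normal(scale=3, size=(8, 3))
            medoids, _, cost = pam_cluster(pts, k=2)
            best_cost, best_sets = pam_exhaustive(pts, 2)
            assert cost == pytest.approx(best_cost, abs=1e-9)
            assert tuple(sorted(medoids)) in [tuple(sorted(s)) for s in best_sets]

    def test_two_blobs_recovered(self, rng):
        pts, truth = blobs(rng, [[0, 0, 0], [20, 0, 0]], 50)
        _, labels, _ = pam_cluster(pts, k=2)
        # labels match blob membership up to relabeling
        assert len(np.unique(labels[truth == 0])) == 1
        assert len(np.unique(labels[truth == 1])) == 1
        assert labels[0] != labels[-1]

    def test_no_improving_swap_remains(self, rng):
        pts = rng.normal(scale=2, size=(15, 3))
        medoids, _, cost = pam_cluster(pts, k=3)
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        for mi in range(3):
            for h in range(15):
                if h in medoids:
                    continue
                trial = [x for j, x in enumerate(medoids) if j != mi] + [h]
                assert dist[:, trial].min(axis=1).sum() >= cost - 1e-9

    def test_k_bounds(self, rng):
        pts = rng.normal(size=(4, 3))
        with pytest.raises(ValueError):
            pam_cluster(pts, k=5)
        with pytest.raises(ValueError):
            pam_cluster(pts, k=0)


class TestChooseK:
    def test_three_separated_blobs(self, rng):
        pts, _ = blobs(rng, [[0, 0, 0], [25, 0, 0], [0, 25, 0]], 30)
        assert choose_k(pts, (2, 6)) == 3

    def test_single_blob_low_silhouette_surfaced(self, rng):
        pts = rng.normal(scale=1.0, size=(30, 3))
        k, scores = choose_k(pts, (2, 3), return_scores=True)
        assert k in (2, 3)
        assert max(scores.values()) < 0.6  # degenerate structure is visible

    def test_duplication_invariance(self, rng):
        pts, _ = blobs(rng, [[0, 0, 0], [25, 0, 0], [0, 25, 0]], 20)
        k1 = choose_k(pts, (2, 5))
        k2 = choose_k(np.concatenate([pts, pts]), (2, 5))
        assert k1 == k2 == 3

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            choose_k(np.zeros((2, 3)), (2, 3))


class TestRegions:
    def test_region_file_round_trip(self, tmp_path):
        regions = [RegionDefinition.catalytic_zone()]
        path = tmp_path / "regions.yaml"
        save_regions(path, regions)
        back = load_regions(path)
        assert back[0].region_name == "catalytic"
        assert back[0].residues == regions[0].residues

    def test_validation_names_missing_residue(self, receptor_and_regions):
        receptor, _ = receptor_and_regions
        bad = RegionDefinition("bogus", [ResidueKey("A", 999, "GLY")])
        with pytest.raises(ValueError, match="999"):
            bad.validate_against(receptor)

    def test_nearby_cluster_assigned_far_cluster_other(self, receptor_and_regions):
        receptor, regions = receptor_and_regions
        cat_anchor = region_anchor(receptor, regions[0])
        coms = np.array([cat_anchor + [0, 0, 3.0], FAR_POINT])
        loc = PoseLocalization(coms, pam_medoids=[0, 1], pam_labels=np.array([0, 1]))
        loc = assign_regions(loc, receptor, regions)
        assert loc.region_assignment[0] == "catalytic"
        assert loc.region_assignment[1] == OTHER_REGION
        assert sum(loc.occupancy.values()) == pytest.approx(1.0, abs=1e-12)

    def test_occupancy_matches_generator_weights(self, receptor_and_regions, rng):
        receptor, regions = receptor_and_regions
        weights = np.array([0.6, 0.3, 0.1])
        anchors = [
            (region_anchor(receptor, regions[0]), weights[0], 2.0),
            (region_anchor(receptor, regions[1]), weights[1], 2.0),
            (FAR_POINT, weights[2], 2.0),
        ]
        poses, components = gen_pose_ensemble(
            peptide_ca_template("L9M"), anchors, rng, n_poses=100
        )
        loc = localize_poses(poses, receptor, regions, k=3)
        se = np.sqrt(weights * (1 - weights) / 100)
        for name, w, s in zip(["catalytic", "mt_loop", OTHER_REGION], weights, se):
            assert abs(loc.occupancy[name] - w) <= 3 * s + 1e-9

    def test_occupancy_invariant_under_joint_rigid_motion(
        self, receptor_and_regions, rng
    ):
        receptor, regions = receptor_and_regions
        anchors = [
            (region_anchor(receptor, regions[0]), 0.5, 2.0),
            (region_anchor(receptor, regions[1]), 0.5, 2.0),
        ]
        poses, _ = gen_pose_ensemble(peptide_ca_template("L9M"), anchors, rng, n_poses=60)
        loc1 = localize_poses(poses, receptor, regions, k=2)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(scale=30, size=3)
        receptor_m = receptor.transformed(R, t)
        poses_m = type(poses)([m.transformed(R, t) for m in poses], label=poses.label)
        loc2 = localize_poses(poses_m, receptor_m, regions, k=2)
        for name in loc1.occupancy:
            assert loc1.occupancy[name] == pytest.approx(loc2.occupancy[name], abs=1e-9)

    def test_exosite_preference_direction(self, receptor_and_regions, rng):
        # a query-like mixture placing most poses at the MT-Loop must yield
        # mt_loop occupancy > catalytic occupancy
        receptor, regions = receptor_and_regions
        anchors = [
            (region_anchor(receptor, regions[1]), 0.6, 2.0),
            (region_anchor(receptor, regions[0]), 0.3, 2.0),
            (FAR_POINT, 0.1, 2.0),
        ]
        poses, _ = gen_pose_ensemble(peptide_ca_template("L9Mc"), anchors, rng, n_poses=100)
        loc = localize_poses(poses, receptor, regions)
        assert loc.occupancy["mt_loop"] > loc.occupancy["catalytic"]
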