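import numpy as np
import pytest

from npckit import refine
from npckit.pipeline import perturb_bodies, toy_two_body
from npckit.refine import (
    ConnectivityPair,
    ElasticPair,
    RestraintSet,
    RigidBody,
    RigidBodyModel,
    clash_score,
    connectivity_score,
    elastic_network_score,
    em_fit_score,
    linker_max_length,
    total_score,
)
from npckit.scaffold import Chain, ScaffoldModel
from npckit.volume import DensityVolume, Pose, ValidationError


def two_bead_model(distance):
    chains = [
        Chain("A", "X", "IR", 0, "s", 0, np.array([[0.0, 0.0, 0.0]])),
        Chain("B", "Y", "IR", 0, "s", 0, np.array([[distance, 0.0, 0.0]])),
    ]
    model = ScaffoldModel(chains, 1)
    return RigidBodyModel(model, [RigidBody([0]), RigidBody([1])])


class TestClashScore:
    def test_far_apart_zero(self):
        assert clash_score(two_bead_model(100.0)) == 0.0

    def test_closed_form_value(self):
        # two beads radius 2 A at distance 3 A, k=1: (2+2-3)^2 = 1.0
        assert clash_score(two_bead_model(3.0), radius=2.0, k=1.0) == \
            pytest.approx(1.0, abs=1e-12)

    def test_non_increasing_when_separating(self):
        scores = [clash_score(two_bead_model(d)) for d in
                  np.linspace(0.5, 6.0, 20)]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_intra_body_contacts_ignored(self):
        chains = [Chain("A", "X", "IR", 0, "s", 0,
                        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])),
                  Chain("B", "Y", "IR", 0, "s", 0,
                        np.array([[50.0, 0.0, 0.0]]))]
        model = RigidBodyModel(ScaffoldModel(chains, 1),
                               [RigidBody([0]), RigidBody([1])])
        assert clash_score(model) == 0.0


class TestConnectivityScore:
    def test_within_bound_zero(self):
        model = two_bead_model(5.0)
        pairs = [ConnectivityPair(0, 0, 1, 0, max_length=38.0)]
        assert connectivity_score(model, pairs) == 0.0

    def test_closed_form_violation(self):
        # 48 A apart with bound 38 A, k=1: (48-38)^2 = 100.0
        model = two_bead_model(48.0)
        pairs = [ConnectivityPair(0, 0, 1, 0, max_length=38.0, k=1.0)]
        assert connectivity_score(model, pairs) == pytest.approx(100.0,
                                                                 abs=1e-9)

    def test_zero_length_linker_at_bond_distance(self):
        model = two_bead_model(3.8)
        pairs = [ConnectivityPair(0, 0, 1, 0,
                                  max_length=linker_max_length(0))]
        assert connectivity_score(model, pairs) == 0.0

    def test_linker_length_rule(self):
        assert linker_max_length(0) == pytest.approx(3.8)
        assert linker_max_length(9) == pytest.approx(38.0)

    def test_dangling_reference_rejected(self):
        model = two_bead_model(5.0)
        pairs = [ConnectivityPair(0, 7, 1, 0, max_length=38.0)]
        with pytest.raises(ValidationError, match="missing residue"):
            connectivity_score(model, pairs)


class TestElasticScore:
    def test_reference_geometry_zero(self):
        rbm, _, restraints = toy_two_body()
        assert elastic_network_score(rbm, restraints.elastic) == \
            pytest.approx(0.0, abs=1e-18)

    def test_closed_form_value(self):
        # one pair, rest 8 A, current 10 A, k=0.5: 0.5*(10-8)^2 = 2.0
        model = two_bead_model(10.0)
        pairs = [ElasticPair(0, 0, 1, 0, rest_length=8.0, k=0.5)]
        assert elastic_network_score(model, pairs) == pytest.approx(2.0,
                                                                    abs=1e-12)

    def test_invariant_under_global_rigid_motion(self):
        rbm, _, restraints = toy_two_body()
        perturb_bodies(rbm, 5.0, 5.0, seed=3)
        before = elastic_network_score(rbm, restraints.elastic)
        g = Pose.from_euler_zyz(30.0, 20.0, 10.0, shift=(5.0, -3.0, 8.0))
        # body poses are centroid-anchored: x' = Rb (x - c) + c + tb, so the
        # globally moved pose is (Rg Rb, Rg (c + tb) + tg - c)
        for body, centroid in zip(rbm.bodies, rbm._centroids):
            rb, tb = body.pose.rotation, body.pose.shift
            body.pose = Pose(g.rotation @ rb,
                             g.rotation @ (centroid + tb) + g.shift - centroid)
        after = elastic_network_score(rbm, restraints.elastic)
        assert after == pytest.approx(before, rel=1e-6, abs=1e-9)

    def test_invalid_rest_length(self):
        with pytest.raises(ValidationError):
            ElasticPair(0, 0, 1, 0, rest_length=0.0)


class TestEmFit:
    def test_self_rendering_near_zero(self):
        rbm, density, restraints = toy_two_body()
        assert em_fit_score(rbm, density,
                            sigma=restraints.render_sigma) < 1e-6

    def test_zero_map_scores_one(self):
        rbm, density, restraints = toy_two_body()
        flat = DensityVolume(np.zeros_like(density.grid), density.voxel_size)
        assert em_fit_score(rbm, flat, sigma=restraints.render_sigma) == \
            pytest.approx(1.0, abs=1e-9)

    def test_translation_increases_score(self):
        rbm, density, restraints = toy_two_body()
        base = em_fit_score(rbm, density, sigma=restraints.render_sigma)
        for body in rbm.bodies:
            body.pose = Pose(np.eye(3), np.array([20.0, 0.0, 0.0]))
        moved = em_fit_score(rbm, density, sigma=restraints.render_sigma)
        assert moved > base + 0.01

    def test_monotone_displacement_sweep(self):
        rbm, density, restraints = toy_two_body()
        scores = []
        for shift in (0.0, 5.0, 10.0, 20.0):
            for body in rbm.bodies:
                body.pose = Pose(np.eye(3), np.array([shift, 0.0, 0.0]))
            scores.append(em_fit_score(rbm, density,
                                       sigma=restraints.render_sigma))
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_empty_model_rejected(self):
        density = DensityVolume(np.zeros((8, 8, 8)), 4.0)
        with pytest.raises(ValidationError):
            em_fit_score(ScaffoldModel([], 1), density)


class TestScoreBreakdown:
    def test_additivity_exact(self):
        rbm, density, restraints = toy_two_body()
        perturb_bodies(rbm, 8.0, 5.0, seed=2)
        breakdown = total_score(rbm, density, restraints)
        expected = (restraints.em_weight * breakdown.em_fit
                    + breakdown.clash + breakdown.connectivity
                    + breakdown.elastic)
        assert breakdown.total == expected   # exact, no tolerance

    def test_truth_is_local_minimum(self):
        rbm, density, restraints = toy_two_body()
        base = total_score(rbm, density, restraints).total
        rng = np.random.default_rng(0)
        for _ in range(50):
            rbm2, _, _ = toy_two_body()
            for body in rbm2.bodies:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = np.radians(rng.uniform(0.5, 2.0))
                kx, ky, kz = axis
                km = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
                rot = (np.eye(3) + np.sin(angle) * km
                       + (1 - np.cos(angle)) * (km @ km))
                body.pose = Pose(rot, rng.normal(0.0, 1.0, size=3))
            assert total_score(rbm2, density, restraints).total > base


class TestRigidBodyModel:
    def test_partition_enforced(self):
        chains = [Chain("A", "X", "IR", 0, "s", 0, np.zeros((2, 3))),
                  Chain("B", "Y", "IR", 0, "s", 0, np.ones((2, 3)))]
        model = ScaffoldModel(chains, 1)
        with pytest.raises(ValidationError, match="partition"):
            RigidBodyModel(model, [RigidBody([0])])

    def test_internal_coordinates_immutable(self):
        rbm, _, _ = toy_two_body()
        ref = rbm.reference.chains[0].coords.copy()
        rbm.bodies[0].pose = Pose(np.eye(3), np.array([30.0, 0.0, 0.0]))
        assert np.array_equal(rbm.reference.chains[0].coords, ref)
        moved = rbm.chain_coords(0)
        assert moved == pytest.approx(ref + np.array([30.0, 0.0, 0.0]))


class TestRefine:
    def test_stable_at_ground_truth(self):
        rbm, density, restraints = toy_two_body()
        rbm, _ = refine.refine(rbm, density, restraints,
                               temperatures=(0.5, 0.1),
                               steps_per_temperature=100, seed=1)
        assert rbm.ca_rmsd_to_reference() < 0.5

    def test_perturbation_recovery_single_seed(self):
        rbm, density, restraints = toy_two_body()
        perturb_bodies(rbm, 15.0, 10.0, seed=5)
        assert rbm.ca_rmsd_to_reference() > 3.0
        rbm, trajectory = refine.refine(
            rbm, density, restraints, temperatures=(5.0, 2.0, 1.0, 0.4, 0.1),
            steps_per_temperature=300, seed=5)
        assert rbm.ca_rmsd_to_reference() < 5.0

    def test_best_total_non_increasing(self):
        rbm, density, restraints = toy_two_body()
        perturb_bodies(rbm, 10.0, 8.0, seed=4)
        _, trajectory = refine.refine(
            rbm, density, restraints, temperatures=(2.0, 0.5),
            steps_per_temperature=100, seed=4)
        best = np.inf
        bests = []
        for step in trajectory:
            best = min(best, step.total)
            bests.append(best)
        assert all(a >= b - 1e-12 for a, b in zip(bests, bests[1:]))

    def test_identical_seeds_identical_trajectories(self):
        out = []
        for _ in range(2):
            rbm, density, restraints = toy_two_body()
            perturb_bodies(rbm, 10.0, 8.0, seed=7)
            _, trajectory = refine.refine(
                rbm, density, restraints, temperatures=(2.0, 0.5),
                steps_per_temperature=80, seed=7)
            out.append([s.total for s in trajectory])
        assert out[0] == out[1]
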