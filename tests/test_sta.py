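import itertools

import numpy as np
import pytest

from npckit import sta, synthetic
from npckit.sta import AlignmentResult
from npckit.volume import (
    DensityVolume,
    Pose,
    ValidationError,
    WedgeModel,
    rotation_about_axis2,
    lowpass,
    transform_volume,
)

from conftest import correlation


# --------------------------------------------------------------------------
# independent brute-force alignment oracle
# --------------------------------------------------------------------------

def brute_force_align(particle, reference, rotations, wedge=None,
                      shift_range=0):
    """Score every (rotation, integer shift) pair independently in real
    space; no FFT correlation, no shared code path with the implementation."""
    def own_wedge_mask(shape, w):
        f0 = np.fft.fftfreq(shape[0])[:, None, None]
        f2 = np.fft.fftfreq(shape[2])[None, None, :]
        ang = np.degrees(np.arctan2(f0, f2))
        ang = ((ang + 90.0) % 180.0) - 90.0
        keep = (ang >= w.tilt_min) & (ang <= w.tilt_max)
        keep |= (f0 == 0) & (f2 == 0)
        return np.broadcast_to(keep, shape)

    def wedge_filter(grid):
        if wedge is None:
            return grid
        f = np.fft.fftn(grid)
        f[~own_wedge_mask(grid.shape, wedge)] = 0
        return np.fft.ifftn(f).real

    p = wedge_filter(particle.grid - particle.grid.mean())
    shifts = range(-shift_range, shift_range + 1)
    best = None
    for ri, rot in enumerate(rotations):
        r = transform_volume(reference.grid, rot)
        r = wedge_filter(r - r.mean())
        for s in itertools.product(shifts, shifts, shifts):
            rs = np.roll(r, s, axis=(0, 1, 2))
            score = (p * rs).sum() / np.sqrt((p * p).sum() * (rs * rs).sum())
            if best is None or score > best[0] + 1e-12:
                best = (score, ri, s)
    return best


class TestAlign:
    def test_self_alignment_identity(self, c1_reference):
        result = sta.align_subtomogram(
            c1_reference, c1_reference,
            rotations=sta.inplane_rotation_grid(45.0))
        assert result.cc_score >= 0.999
        assert result.pose.angle_to(Pose.identity()) == pytest.approx(0.0,
                                                                      abs=1e-9)
        assert np.allclose(result.pose.shift, 0.0)

    def test_on_grid_rotation_recovered_exactly(self, c1_reference):
        true_pose = Pose(rotation_about_axis2(120.0))
        particle = synthetic.simulate_particles(
            c1_reference, 1, 0.0, wedge=None,
            pose_distribution=lambda rng: true_pose, seed=0)[0]
        result = sta.align_subtomogram(
            particle.subtomogram, c1_reference,
            rotations=sta.inplane_rotation_grid(30.0))
        assert result.pose.angle_to(true_pose) == pytest.approx(0.0, abs=1e-6)

    def test_on_grid_shift_recovered(self, c1_reference):
        true_pose = Pose(np.eye(3), np.array([0.0, 20.0, -10.0]))
        particle = synthetic.simulate_particles(
            c1_reference, 1, 0.0, wedge=None,
            pose_distribution=lambda rng: true_pose, seed=0)[0]
        result = sta.align_subtomogram(
            particle.subtomogram, c1_reference, shift_limit=30.0,
            rotations=[np.eye(3)])
        assert result.pose.shift == pytest.approx(true_pose.shift, abs=1e-6)

    def test_matches_brute_force_oracle(self, c1_reference_small,
                                        standard_wedge):
        rotations = sta.inplane_rotation_grid(45.0)
        rng_angles = [100.0, 225.0, 315.0]
        for i, ang in enumerate(rng_angles):
            particle = synthetic.simulate_particles(
                c1_reference_small, 1, 0.15, standard_wedge,
                pose_distribution=lambda rng, a=ang: Pose(
                    rotation_about_axis2(a)), seed=i)[0]
            result = sta.align_subtomogram(
                particle.subtomogram, c1_reference_small,
                wedge=standard_wedge, rotations=rotations)
            _, best_ri, _ = brute_force_align(
                particle.subtomogram, c1_reference_small, rotations,
                wedge=standard_wedge)
            assert np.allclose(result.pose.rotation, rotations[best_ri])

    def test_matches_brute_force_with_shifts(self, c1_reference_small):
        true_pose = Pose(rotation_about_axis2(90.0),
                         np.array([10.0, -10.0, 0.0]))
        particle = synthetic.simulate_particles(
            c1_reference_small, 1, 0.0, wedge=None,
            pose_distribution=lambda rng: true_pose, seed=0)[0]
        rotations = sta.inplane_rotation_grid(90.0)
        result = sta.align_subtomogram(
            particle.subtomogram, c1_reference_small, shift_limit=20.0,
            rotations=rotations)
        _, best_ri, best_shift = brute_force_align(
            particle.subtomogram, c1_reference_small, rotations,
            shift_range=2)
        assert np.allclose(result.pose.rotation, rotations[best_ri])
        assert result.pose.shift == pytest.approx(
            np.array(best_shift) * 10.0, abs=1e-6)

    def test_empty_mask_rejected(self, c1_reference):
        empty = DensityVolume(np.zeros_like(c1_reference.grid),
                              c1_reference.voxel_size)
        with pytest.raises(ValidationError, match="mask"):
            sta.align_subtomogram(c1_reference, c1_reference, mask=empty,
                                  rotations=[np.eye(3)])

    def test_excessive_shift_limit_rejected(self, c1_reference):
        with pytest.raises(ValidationError, match="shift_limit"):
            sta.align_subtomogram(c1_reference, c1_reference,
                                  shift_limit=1e4, rotations=[np.eye(3)])

    def test_recovery_at_low_snr(self, c1_reference, standard_wedge):
        sigma = c1_reference.grid.std() * np.sqrt(2.0)   # SNR ~ 0.5
        particles = synthetic.simulate_particles(
            c1_reference, 20, sigma, standard_wedge,
            pose_distribution="uniform_inplane", seed=1)
        results = sta.align_stack(particles, c1_reference,
                                  wedge=standard_wedge,
                                  rotations=sta.inplane_rotation_grid(10.0))
        errors = [r.pose.angle_to(p.true_pose)
                  for r, p in zip(results, particles)]
        within = sum(e <= 10.0 + 1e-6 for e in errors)
        assert within >= 18    # >= 90%


class TestAverage:
    def test_identity_copies_reproduce_reference(self, c1_reference):
        n = 4
        avg = sta.average_subtomograms(
            [c1_reference] * n, [Pose.identity()] * n, [None] * n)
        assert avg.grid == pytest.approx(
            c1_reference.grid, abs=1e-6 * np.abs(c1_reference.grid).max())

    def test_posed_copies_reproduce_reference(self, c1_reference):
        poses = [Pose(rotation_about_axis2(a)) for a in (0.0, 90.0, 180.0)]
        particles = [
            synthetic.simulate_particles(
                c1_reference, 1, 0.0, None,
                pose_distribution=lambda rng, p=pose: p, seed=0)[0]
            for pose in poses]
        avg = sta.average_subtomograms(particles, poses)
        assert correlation(avg.grid, c1_reference.grid) > 0.99

    def test_wedge_compensation_union_support(self, c1_reference,
                                              standard_wedge):
        from npckit.volume import rotate_fourier_mask, wedge_mask

        rot90 = Pose(rotation_about_axis2(90.0))
        parts = [
            synthetic.simulate_particles(
                c1_reference, 1, 0.0, standard_wedge,
                pose_distribution=lambda rng, p=pose: p, seed=0)[0]
            for pose in (Pose.identity(), rot90)]
        avg = sta.average_subtomograms(parts, [p.true_pose for p in parts])
        w = wedge_mask(c1_reference.shape, standard_wedge)
        union = w | rotate_fourier_mask(w, rot90.inverse().rotation)
        f = np.abs(np.fft.fftn(avg.grid))
        # outside the union the average must be (numerically) zero
        assert f[~union].max() < 1e-3 * f.max()
        # the union support carries most of the reference's power there
        f_ref = np.abs(np.fft.fftn(c1_reference.grid))
        assert (f[union] > 0).any()
        assert f_ref[union].sum() > f_ref.sum() * 0.75

    def test_correlation_monotone_in_n(self, c1_reference, standard_wedge):
        sigma = c1_reference.grid.std() * np.sqrt(2.0)
        particles = synthetic.simulate_particles(
            c1_reference, 32, sigma, standard_wedge,
            pose_distribution="uniform_inplane", seed=3)
        corrs = []
        for n in (2, 8, 32):
            avg = sta.average_subtomograms(
                particles[:n], [p.true_pose for p in particles[:n]])
            corrs.append(correlation(avg.grid, c1_reference.grid))
        assert corrs[0] < corrs[1] < corrs[2]

    def test_empty_stack_rejected(self):
        with pytest.raises(ValidationError):
            sta.average_subtomograms([], [])


class TestSymmetryExpand:
    def test_identity_pose_angles(self):
        expanded = sta.symmetry_expand(Pose.identity(), np.zeros(3),
                                       order=8, spoke_radius=350.0)
        assert len(expanded) == 8
        for k, (_pos, pose) in enumerate(expanded):
            expected = Pose(rotation_about_axis2(45.0 * k))
            assert pose.angle_to(expected) == pytest.approx(0.0, abs=1e-5)

    def test_positions_on_circle(self):
        centre = np.array([10.0, -5.0, 3.0])
        whole = Pose.from_euler_zyz(20.0, 30.0, 40.0)
        expanded = sta.symmetry_expand(whole, centre, order=8,
                                       spoke_radius=350.0)
        for pos, _pose in expanded:
            assert np.linalg.norm(pos - centre) == pytest.approx(350.0,
                                                                 abs=1e-9)

    def test_group_closure_under_extra_rotation(self):
        whole = Pose.from_euler_zyz(10.0, 25.0, -40.0)
        centre = np.zeros(3)
        expanded = sta.symmetry_expand(whole, centre, order=8,
                                       spoke_radius=100.0)
        extra = Pose(whole.rotation @ rotation_about_axis2(45.0)
                     @ whole.rotation.T)
        rotated = [(extra.rotation @ pos, Pose(extra.rotation @ pose.rotation,
                                               extra.rotation @ pose.shift))
                   for pos, pose in expanded]
        for pos_r, pose_r in rotated:
            matched = any(
                np.abs(pos_r - pos).max() < 1e-6
                and np.abs(pose_r.rotation - pose.rotation).max() < 1e-6
                for pos, pose in expanded)
            assert matched

    def test_invalid_order(self):
        with pytest.raises(ValidationError):
            sta.symmetry_expand(Pose.identity(), np.zeros(3), order=0)


class TestFSC:
    def test_self_fsc_is_one(self, c1_reference):
        curve = sta.fsc(c1_reference, c1_reference)
        assert curve.correlations == pytest.approx(
            np.ones_like(curve.correlations), abs=1e-6)

    def test_independent_noise_low_fsc(self):
        rng = np.random.default_rng(5)
        a = DensityVolume(rng.normal(size=(64,) * 3), 5.0)
        b = DensityVolume(rng.normal(size=(64,) * 3), 5.0)
        # two-voxel shells: enough samples per shell for a stable estimate
        curve = sta.fsc(a, b, shell_width=2.0 / (64 * 5.0))
        assert np.abs(curve.correlations[1:]).max() < 0.2

    def test_band_limit_recovered(self):
        rng = np.random.default_rng(5)
        signal = lowpass(rng.normal(size=(64,) * 3), 5.0, 35.0)
        h1 = DensityVolume(signal + 0.18 * rng.normal(size=(64,) * 3), 5.0)
        h2 = DensityVolume(signal + 0.18 * rng.normal(size=(64,) * 3), 5.0)
        curve = sta.fsc(h1, h2)
        res = sta.resolution_at(curve, 0.143)
        crossing_freq = 1.0 / res
        assert abs(crossing_freq - 1.0 / 35.0) <= 2 * curve.shell_width

    def test_mismatched_grids_rejected(self):
        a = DensityVolume(np.zeros((16,) * 3), 1.0)
        b = DensityVolume(np.zeros((12,) * 3), 1.0)
        with pytest.raises(ValidationError):
            sta.fsc(a, b)

    def test_resolution_threshold_monotone(self):
        rng = np.random.default_rng(7)
        signal = lowpass(rng.normal(size=(32,) * 3), 4.0, 20.0)
        h1 = DensityVolume(signal + 0.3 * rng.normal(size=(32,) * 3), 4.0)
        h2 = DensityVolume(signal + 0.3 * rng.normal(size=(32,) * 3), 4.0)
        curve = sta.fsc(h1, h2)
        resolutions = []
        for threshold in (0.5, 0.143, 0.05):
            res = sta.resolution_at(curve, threshold)
            resolutions.append(np.inf if res is None else res)
        # lower threshold never gives a worse (larger) resolution
        assert resolutions[0] >= resolutions[1] >= resolutions[2]


class TestIterativeRefine:
    def _perturbed_stack(self, reference, n, sigma, seed):
        return synthetic.simulate_particles(
            reference, n, sigma, None,
            pose_distribution="uniform_inplane", seed=seed)

    def test_noiseless_convergence(self, c1_reference):
        particles = self._perturbed_stack(c1_reference, 6, 0.0, seed=2)
        rotations = sta.inplane_rotation_grid(30.0)
        _avg, poses, _curve = sta.iterative_refine(
            particles, c1_reference, n_iter=2, rotations=rotations)
        for pose, particle in zip(poses, particles):
            assert pose.angle_to(particle.true_pose) <= 15.0 + 1e-6

    def test_determinism(self, c1_reference):
        particles = self._perturbed_stack(c1_reference, 5, 0.2, seed=1)
        rotations = sta.inplane_rotation_grid(30.0)
        out1 = sta.iterative_refine(particles, c1_reference, n_iter=2,
                                    rotations=rotations, seed=1)
        out2 = sta.iterative_refine(particles, c1_reference, n_iter=2,
                                    rotations=rotations, seed=1)
        assert np.array_equal(out1[0].grid, out2[0].grid)
        for p1, p2 in zip(out1[1], out2[1]):
            assert np.array_equal(p1.rotation, p2.rotation)

    def test_improves_over_blurred_initial_reference(self, c1_reference,
                                                     standard_wedge):
        sigma = c1_reference.grid.std() * np.sqrt(2.0)
        particles = synthetic.simulate_particles(
            c1_reference, 16, sigma, standard_wedge,
            pose_distribution="uniform_inplane", seed=2)
        initial = DensityVolume(
            lowpass(c1_reference.grid, c1_reference.voxel_size, 120.0),
            c1_reference.voxel_size)
        final, _poses, _curve = sta.iterative_refine(
            particles, initial, wedge=standard_wedge, n_iter=3,
            rotations=sta.inplane_rotation_grid(15.0), seed=2)
        assert correlation(final.grid, c1_reference.grid) > \
            correlation(initial.grid, c1_reference.grid)


class TestCleanParticles:
    def _results(self, scores):
        return [AlignmentResult(Pose.identity(), s, particle_id=i)
                for i, s in enumerate(scores)]

    def test_no_floor_identity(self):
        results = self._results([0.1, 0.5, -0.3])
        assert sta.clean_particles(results, cc_floor=-1.0) == results

    def test_all_rejected_with_warning(self, caplog):
        results = self._results([0.1, 0.2])
        with caplog.at_level("WARNING"):
            kept = sta.clean_particles(results, cc_floor=0.9)
        assert kept == []
        assert any("rejected" in r.message for r in caplog.records)

    def test_mixed_floor_and_reject_list(self):
        scores = [0.9, 0.1, 0.8, 0.05, 0.7, 0.02, 0.6, 0.5, 0.4, 0.95]
        results = self._results(scores)
        kept = sta.clean_particles(results, cc_floor=0.3)
        assert len(kept) == 7
        assert [k.particle_id for k in kept] == [0, 2, 4, 6, 7, 8, 9]
        kept2 = sta.clean_particles(results, cc_floor=0.3,
                                    manual_reject_list=[0, 9])
        assert len(kept2) == 5


class TestBinning:
    def test_bin_by_two(self, c1_reference):
        binned = sta.bin_volume(c1_reference, 2)
        assert binned.shape == (16, 16, 16)
        assert binned.voxel_size == pytest.approx(20.0)
        small = transform_volume(binned.grid, np.eye(3))
        assert correlation(small, c1_reference.grid[::2, ::2, ::2]) > 0.9

    def test_invalid_factor(self, c1_reference):
        with pytest.raises(ValidationError):
            sta.bin_volume(c1_reference, 3)   # 32 not divisible
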