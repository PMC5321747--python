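"""Constrained correlation, pair alignment, averaging, template matching."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import tomodiff as td
from tomodiff import align as al
from tomodiff.particles import Subtomogram, apply_support, make_wedge_support
from tomodiff.transforms import RigidTransform, apply_transform
from tomodiff.volmap import DensityMap


class TestConstrainedCC:
    def test_self_and_anti_correlation(self, rng):
        a = rng.standard_normal((8, 8, 8))
        assert al.constrained_cc(a, a) == pytest.approx(1.0, abs=1e-6)
        assert al.constrained_cc(a, -a) == pytest.approx(-1.0, abs=1e-6)

    def test_full_support_equals_pearson(self, rng):
        for _ in range(200):
            a = rng.standard_normal((8, 8, 8))
            b = rng.standard_normal((8, 8, 8))
            expect = np.corrcoef(a.ravel(), b.ravel())[0, 1]
            assert al.constrained_cc(a, b) == pytest.approx(expect, abs=1e-6)

    def test_affine_intensity_invariance(self, rng):
        a = rng.standard_normal((8, 8, 8))
        b = rng.standard_normal((8, 8, 8))
        base = al.constrained_cc(a, b)
        assert al.constrained_cc(3.2 * a + 1.7, b) == pytest.approx(base, abs=1e-9)
        assert al.constrained_cc(a, 0.4 * b - 2.0) == pytest.approx(base, abs=1e-9)

    def test_disjoint_supports_raise(self, rng):
        a = rng.standard_normal((8, 8, 8))
        sa = np.zeros((8, 8, 8), bool)
        sb = np.zeros((8, 8, 8), bool)
        sa[0, 0, 0] = True
        sb[7, 7, 7] = True
        with pytest.raises(ValueError, match="disjoint"):
            al.constrained_cc(a, a, sa, sb)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            al.constrained_cc(rng.standard_normal((8, 8, 8)),
                              rng.standard_normal((9, 9, 9)))

    def test_wedge_restriction_changes_nothing_for_wedge_limited_pair(self, wedge, rng):
        """Volumes already band-limited to the wedge score identically with
        and without declaring the support (no information outside it)."""
        sup = make_wedge_support(wedge, 16)
        a = apply_support(rng.standard_normal((16, 16, 16)), sup)
        b = apply_support(rng.standard_normal((16, 16, 16)), sup)
        assert al.constrained_cc(a, b, sup, sup) == pytest.approx(
            al.constrained_cc(a, b), abs=1e-6
        )


class TestAlignPair:
    def test_noiseless_identity_recovery(self, phantom, full_wedge):
        s = td.simulate_subtomogram(phantom, RigidTransform(), full_wedge, None, 0)
        pose, score = al.align_pair(s, phantom, angular_step=90.0, max_shift=3)
        assert pose.euler == (0.0, 0.0, 0.0)
        assert np.allclose(pose.shift, 0.0)
        assert score == pytest.approx(1.0, abs=1e-3)

    def test_integer_circular_shift_recovered_exactly(self, phantom, wedge):
        """A circularly shifted copy is the exact fixed point of FFT
        cross-correlation: integer shift recovered with no error."""
        sup = make_wedge_support(wedge, phantom.shape)
        base = apply_support(phantom.values.astype(float), sup)
        shifted = np.roll(base, (3, -2, 5), axis=(0, 1, 2))
        s = Subtomogram(map=DensityMap(shifted.astype(np.float32), 5.0), wedge=wedge)
        pose, score = al.align_pair(s, phantom, angular_step=0,
                                    candidates=[(0.0, 0.0, 0.0)], max_shift=6)
        assert tuple(pose.shift) == (-3.0, 2.0, -5.0)
        assert score == pytest.approx(1.0, abs=1e-3)

    def test_rotation_on_grid_recovered_noiseless(self, phantom, wedge):
        true = (40.0, 60.0, 120.0)
        place = RigidTransform.from_rotation(
            Rotation.from_euler("ZYZ", true, degrees=True).inv()
        )
        s = td.simulate_subtomogram(phantom, place, wedge, None, 1)
        cands = [(0.0, 0.0, 0.0), (40.0, 60.0, 120.0), (80.0, 120.0, 240.0),
                 (200.0, 20.0, 40.0)]
        pose, score = al.align_pair(s, phantom, 0, candidates=cands, max_shift=4)
        assert pose.euler == true
        assert score > 0.9

    def test_alignment_consistency_composed_transform(self, phantom, full_wedge):
        """Aligning against a rotated reference returns the composed pose."""
        rot = Rotation.from_euler("ZYZ", [90.0, 0.0, 0.0], degrees=True)
        ref_rot = DensityMap(
            apply_transform(phantom.values, RigidTransform.from_rotation(rot)).astype(np.float32),
            phantom.voxel_size,
        )
        s = td.simulate_subtomogram(phantom, RigidTransform(), full_wedge, None, 0)
        pose, _ = al.align_pair(s, ref_rot, angular_step=90.0, max_shift=2)
        rel = (pose.rotation * rot.inv()).magnitude() * 180 / np.pi
        assert rel < 1e-6


class TestAveraging:
    def test_single_particle_identity_pose(self, phantom, wedge):
        s = td.simulate_subtomogram(phantom, RigidTransform(), wedge, None, 0)
        avg = al.wedge_compensated_average([s], [RigidTransform()])
        assert np.allclose(avg.values, s.map.values, atol=1e-4)

    def test_same_wedge_identity_poses_equals_voxel_mean_in_passband(self, phantom, wedge, rng):
        subs = [
            td.simulate_subtomogram(phantom, RigidTransform(), wedge, 1.0, seed)
            for seed in range(8)
        ]
        avg = al.wedge_compensated_average(subs, [RigidTransform()] * 8)
        plain = np.mean([s.map.values for s in subs], axis=0)
        sup = make_wedge_support(wedge, phantom.shape)
        fa = np.fft.fftshift(np.fft.fftn(avg.values.astype(float)))[sup]
        fp = np.fft.fftshift(np.fft.fftn(plain.astype(float)))[sup]
        assert np.allclose(fa, fp, rtol=1e-4, atol=1e-3)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            al.wedge_compensated_average([])

    def test_averaging_beats_best_single_particle(self, pspec, wedge):
        """SNR gain: the 64-particle average correlates better with the
        phantom than any individual particle does."""
        phant = td.build_phantom(pspec)
        spec = td.DatasetSpec(n_particles=64, occupancy={}, snr=0.5, seed=13)
        subs, gt = td.generate_dataset(spec, pspec, wedge)
        from tomodiff.phantom import poses_from_table
        poses = poses_from_table(gt)
        avg = al.wedge_compensated_average(subs, poses)
        c_avg = al.constrained_cc(avg.values, phant.values)
        singles = [
            al.constrained_cc(apply_transform(s.map.values.astype(float), p), phant.values)
            for s, p in zip(subs[:16], poses[:16])
        ]
        assert c_avg > max(singles)

    def test_one_extra_iteration_after_convergence_is_stable(self, pspec, full_wedge):
        phant = td.build_phantom(pspec)
        subs = [
            td.simulate_subtomogram(phant, RigidTransform(), full_wedge, None, i)
            for i in range(3)
        ]
        sched = [{"step": 30.0, "local": True, "bin": 1}]
        avg1, poses1, _, _ = al.iterative_average(subs, phant, schedule=sched)
        avg2, poses2, _, _ = al.iterative_average(subs, avg1, schedule=sched)
        rms = np.sqrt(np.mean((avg2.values - avg1.values) ** 2))
        assert rms < 1e-3 * np.abs(avg1.values).max()

    def test_mean_score_nondecreasing_over_refinement(self, pspec, wedge):
        phant = td.build_phantom(pspec)
        spec = td.DatasetSpec(n_particles=6, occupancy={}, snr=1.0, seed=2)
        subs, _ = td.generate_dataset(spec, pspec, wedge)
        sched = [
            {"step": 45.0, "local": False, "bin": 1},
            {"step": 22.5, "local": True, "bin": 1},
            {"step": 11.25, "local": True, "bin": 1},
        ]
        _, _, _, hist = al.iterative_average(subs, phant, schedule=sched,
                                             bandpass=(None, 20.0))
        scores = [h["mean_score"] for h in hist]
        assert all(b >= a - 1e-3 for a, b in zip(scores, scores[1:]))


class TestTemplateMatch:
    # particle-like plants (no membrane slab: the template is the complex,
    # matching practice of locating particles with a compact reference) at
    # separations larger than the particle diameter
    def _tomogram_with_plants(self, pspec, wedge, positions, snr=None, seed=0):
        phant = td.build_phantom(pspec, membrane=False)
        big = (120, 120, 120)
        tomo = np.zeros(big)
        half = pspec.box_size // 2
        for p in positions:
            sl = tuple(slice(c - half, c + half) for c in p)
            tomo[sl] += phant.values
        sup = make_wedge_support(wedge, big)
        tomo = apply_support(tomo, sup)
        if snr is not None:
            sig = tomo[tomo > 0.1 * tomo.max()].var()
            tomo = tomo + np.random.default_rng(seed).normal(
                0, np.sqrt(sig / snr), big
            )
        return DensityMap(tomo.astype(np.float32), pspec.voxel_size), phant

    def test_planted_match_found_exactly(self, pspec, wedge):
        tomo, phant = self._tomogram_with_plants(pspec, wedge, [(40, 60, 50)])
        peaks = al.template_match(tomo, phant, wedge, n_peaks=1,
                                  candidates=[(0.0, 0.0, 0.0)])
        assert (peaks.x[0], peaks.y[0], peaks.z[0]) == (40, 60, 50)
        assert peaks.score[0] > 0.9

    def test_planted_particles_recalled_under_noise(self, pspec, wedge):
        truth = [(30, 30, 30), (90, 30, 30), (30, 90, 30), (30, 30, 90), (90, 90, 90)]
        tomo, phant = self._tomogram_with_plants(pspec, wedge, truth, snr=1.0, seed=4)
        peaks = al.template_match(tomo, phant, wedge, n_peaks=5,
                                  candidates=[(0.0, 0.0, 0.0)])
        found = peaks[["x", "y", "z"]].values
        for t in truth:
            d = np.linalg.norm(found - np.array(t), axis=1).min()
            assert d <= 2.0

    def test_noise_scores_below_planted_scores(self, pspec, wedge):
        tomo, phant = self._tomogram_with_plants(pspec, wedge, [(60, 60, 60)],
                                                 snr=1.0, seed=9)
        rng = np.random.default_rng(9)
        pure = DensityMap(
            rng.normal(0, tomo.values.std(), tomo.shape).astype(np.float32),
            pspec.voxel_size,
        )
        p1 = al.template_match(tomo, phant, wedge, n_peaks=1, candidates=[(0.0, 0.0, 0.0)])
        p0 = al.template_match(pure, phant, wedge, n_peaks=1, candidates=[(0.0, 0.0, 0.0)])
        assert p0.score[0] < p1.score[0]

    def test_template_larger_than_tomogram_rejected(self, pspec, wedge, phantom):
        small = DensityMap(np.zeros((16, 16, 16), np.float32), pspec.voxel_size)
        with pytest.raises(ValueError):
            al.template_match(small, phantom, wedge)
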