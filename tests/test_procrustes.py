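"""GPA, Procrustes distances and tangent-space machinery."""

import math

import numpy as np
import pytest

from sporemorph.procrustes import (LandmarkDataset, centroid_size, gpa,
                                   optimal_rotation, procrustes_distance,
                                   tangent_projection, tangent_space_check)

TRI_A = np.array([[0.0, 0.0], [1.0, 0.0], [0.2, 0.9]])
TRI_B = np.array([[0.1, -0.1], [0.9, 0.3], [0.0, 1.1]])


def unit(config):
    c = config - config.mean(0)
    return c / np.linalg.norm(c)


def brute_force_superimpose(a, b, step=1e-4):
    """Grid search over rotation angle for the minimal residual SS."""
    za, zb = unit(a), unit(b)
    best = np.inf
    angles = np.arange(0.0, 2 * np.pi, step)
    ca, sa = np.cos(angles), np.sin(angles)
    # rotate za by each angle and compare to zb
    x, y = za[:, 0], za[:, 1]
    for c, s in zip(ca, sa):
        rx = c * x - s * y
        ry = s * x + c * y
        ss = np.sum((rx - zb[:, 0]) ** 2 + (ry - zb[:, 1]) ** 2)
        best = min(best, ss)
    return best


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        pts = np.array([[0.5, 0.5], [-0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        assert centroid_size(pts) == pytest.approx(math.sqrt(2.0))

    def test_scaling(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        assert centroid_size(3.7 * pts) == pytest.approx(3.7 * centroid_size(pts))

    def test_degenerate(self):
        with pytest.raises(ValueError):
            centroid_size(np.ones((5, 2)))


class TestOptimalRotation:
    def test_matches_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=(8, 2))
            a -= a.mean(0)
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[math.cos(theta), -math.sin(theta)],
                            [math.sin(theta), math.cos(theta)]])
            b = a @ rot.T
            est = optimal_rotation(a, b)
            assert np.allclose(est, rot, atol=1e-10)
            assert np.linalg.det(est) == pytest.approx(1.0)


class TestGPA:
    def test_identical_up_to_similarity_collapses(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 2))
        configs = []
        for _ in range(6):
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[math.cos(theta), -math.sin(theta)],
                            [math.sin(theta), math.cos(theta)]])
            configs.append(rng.uniform(0.5, 2.0) * base @ rot.T
                           + rng.normal(size=2))
        res = gpa(np.stack(configs))
        assert res.converged
        spread = res.aligned - res.aligned.mean(0)
        assert np.abs(spread).max() < 1e-9

    def test_unit_size_and_consensus_invariants(self, averaged):
        res = gpa(averaged)
        cs = np.sqrt(np.sum(res.aligned ** 2, axis=(1, 2)))
        assert np.allclose(cs, 1.0, atol=1e-10)
        assert np.allclose(res.aligned.mean(axis=(1,)).mean(0),
                           res.consensus.mean(0), atol=1e-8)
        # consensus is the normalized mean of aligned configurations
        mean = res.aligned.mean(0)
        mean = mean - mean.mean(0)
        mean /= np.linalg.norm(mean)
        assert np.allclose(mean, res.consensus, atol=1e-8)

    def test_two_triangles_match_rotation_grid_oracle(self):
        res = gpa(np.stack([TRI_A, TRI_B]))
        ss_gpa = float(np.sum((res.aligned[0] - res.aligned[1]) ** 2))
        ss_brute = brute_force_superimpose(TRI_A, TRI_B)
        assert ss_gpa == pytest.approx(ss_brute, abs=1e-6)

    def test_specimen_order_invariance(self, averaged):
        res = gpa(averaged)
        perm = np.random.default_rng(3).permutation(len(averaged))
        res_p = gpa(averaged[perm])
        assert np.allclose(res_p.consensus, res.consensus, atol=1e-9)
        assert np.allclose(res_p.aligned, res.aligned[perm], atol=1e-9)

    def test_dataset_input_flattens_replicates(self, dataset):
        res = gpa(dataset)
        assert len(res.aligned) == dataset.n_specimens * dataset.n_replicates


class TestProcrustesDistance:
    def test_similarity_invariance(self):
        theta = 0.8
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        b = 2.0 * TRI_A @ rot.T + [5, 6]
        assert procrustes_distance(TRI_A, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_rotation_grid(self):
        d = procrustes_distance(TRI_A, TRI_B)
        assert d * d == pytest.approx(brute_force_superimpose(TRI_A, TRI_B),
                                      abs=1e-6)

    def test_mirror_image_distance_positive(self):
        assert procrustes_distance(TRI_A, TRI_A * [-1, 1]) > 0.05

    def test_geodesic_relation(self):
        d = procrustes_distance(TRI_A, TRI_B)
        rho = procrustes_distance(TRI_A, TRI_B, kind="geodesic")
        assert rho == pytest.approx(2 * math.asin(d / 2))


class TestTangentSpace:
    def test_consensus_maps_to_zero(self, averaged):
        res = gpa(averaged)
        c = res.consensus / np.linalg.norm(res.consensus)
        t = tangent_projection(res)
        # a pseudo-specimen equal to the consensus has zero tangent vector
        res2 = gpa(np.concatenate([averaged, [res.consensus]], axis=0))
        t2 = tangent_projection(res2)
        assert np.linalg.norm(t2[-1]) < 1e-6
        assert np.abs(t.mean(axis=0)).max() < 1e-4

    def test_total_tangent_ss_approximates_procrustes_ss(self, averaged,
                                                         default_spec):
        # at the calibrated (large) shape variation the curvature correction
        # cos^2(rho/2) caps agreement near one percent ...
        res = gpa(averaged)
        t = tangent_projection(res)
        ss_t = float(np.sum(t ** 2))
        d2 = [procrustes_distance(a, res.consensus) ** 2 for a in averaged]
        assert ss_t == pytest.approx(sum(d2), rel=2e-2)
        # ... and becomes first-order exact as the variation shrinks
        from dataclasses import replace
        from sporemorph.simulate import sample_population
        small = replace(default_spec, host_sizes=(8, 6, 7, 6, 13),
                        mode1_sd=default_spec.mode1_sd * 0.03,
                        mode2_sd=default_spec.mode2_sd * 0.03,
                        host_shape_shift_sd=0.0, allometric_slope=0.0,
                        asymmetry_sd=default_spec.asymmetry_sd * 0.03,
                        directional_asymmetry=0.0, seed=61)
        configs = np.stack([lm.coords for lm
                            in sample_population(small).true_landmarks])
        res_s = gpa(configs)
        ss_small = float(np.sum(tangent_projection(res_s) ** 2))
        d2s = [procrustes_distance(a, res_s.consensus) ** 2 for a in configs]
        assert ss_small == pytest.approx(sum(d2s), rel=1e-4)

    def test_adequacy_check_near_one_for_default_cohort(self, averaged):
        slope, corr = tangent_space_check(gpa(averaged))
        assert corr > 0.99
        assert 0.95 < slope <= 1.0

    def test_adequacy_degrades_with_larger_variation(self, averaged):
        res = gpa(averaged)
        _, corr1 = tangent_space_check(res)
        # doubling the shape deviations about the consensus
        inflated = res.consensus + 2.0 * (res.aligned - res.consensus)
        _, corr2 = tangent_space_check(gpa(inflated))
        assert corr2 <= corr1 + 1e-12


def test_dataset_validation():
    good = np.zeros((3, 2, 8, 2))
    good[..., 0] = np.arange(8)
    with pytest.raises(ValueError):
        LandmarkDataset(coords=np.full((3, 2, 8, 2), np.nan),
                        host_id=np.ones(3), specimen_id=np.arange(3),
                        replicate_id=np.arange(2))
    ds = LandmarkDataset(coords=good, host_id=np.ones(3),
                         specimen_id=np.arange(3), replicate_id=np.arange(2))
    assert ds.replicate_mean().shape == (3, 8, 2)
    assert ds.flattened().shape == (6, 8, 2)
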