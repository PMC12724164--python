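"""Sphere fitting, robust covariance, alignment and scaling."""

import numpy as np
import pytest

from dendromorph import (align_dendrite, align_population, fit_sphere,
                         pc1_axis_angle, robust_covariance, scale_dendrite,
                         variance_explained)
from dendromorph.align import AlignmentFrame, _rotation_from_eigvecs

from conftest import build_tree


def sphere_points(center, radius, n, rng, noise=0.0):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = center + radius * v
    if noise:
        pts = pts + rng.normal(0, noise, size=pts.shape)
    return pts


def elliptical_cloud(n, axes=(1.0, 4.0, 0.3), seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, 3)) * np.asarray(axes)


def cloud_tree(points, root_at_origin=True):
    pos = {i: p for i, p in enumerate(points)}
    if root_at_origin:
        pos[0] = np.zeros(3)
    edges = [(0, i) for i in range(1, len(points))]
    return build_tree(edges, pos)


class TestSphereFit:
    def test_exact_recovery(self):
        rng = np.random.default_rng(1)
        fit = fit_sphere(sphere_points(np.array([1.0, 2.0, 3.0]), 50.0, 100, rng))
        assert np.allclose(fit.center, [1, 2, 3], atol=1e-6)
        assert fit.radius == pytest.approx(50.0, abs=1e-6)
        assert fit.rms_residual < 1e-6 * fit.radius

    def test_noisy_recovery(self):
        rng = np.random.default_rng(2)
        fit = fit_sphere(
            sphere_points(np.zeros(3), 50.0, 2000, rng, noise=0.1)
        )
        assert fit.radius == pytest.approx(50.0, abs=0.05)

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ValueError, match="degenerate"):
            fit_sphere(pts)


class TestRobustCovariance:
    def test_clean_gaussian_matches_classical(self):
        x = elliptical_cloud(10000, seed=3)
        _, rob = robust_covariance(x)
        ev_r = np.sort(np.linalg.eigvalsh(rob))
        ev_c = np.sort(np.linalg.eigvalsh(np.cov(x.T)))
        assert np.allclose(ev_r, ev_c, rtol=0.05)

    def test_outlier_resistance_along_z(self):
        rng = np.random.default_rng(4)
        clean = rng.normal(size=(2000, 3)) * np.array([3.0, 2.0, 1.0])
        outliers = rng.normal(size=(100, 3)) * np.array([1.0, 1.0, 40.0])
        x = np.vstack([clean, outliers])
        lam3_true = 1.0
        _, rob = robust_covariance(x)
        # contaminated axis = largest eigenvalue of the classical estimate
        lam_rob = np.sort(np.linalg.eigvalsh(rob))
        lam_cls = np.sort(np.linalg.eigvalsh(np.cov(x.T)))
        assert lam_rob[0] < 1.3 * lam3_true  # bounded influence: mild inflation
        assert lam_cls[-1] > 10.0 * lam3_true  # classical blows up on z
        # the clean axes stay close to truth
        assert np.allclose(lam_rob[1:], [4.0, 9.0], rtol=0.15)

    def test_degenerate_points_fall_back(self):
        x = np.zeros((10, 3))
        x[:, 0] = np.arange(10)
        with pytest.warns(UserWarning, match="classical fallback"):
            robust_covariance(x)


class TestAlignDendrite:
    def test_already_aligned_cloud_keeps_orientation(self):
        pts = elliptical_cloud(500, axes=(1.0, 5.0, 0.2), seed=5)
        t = cloud_tree(pts)
        _, frame = align_dendrite(t)
        assert np.allclose(np.abs(frame.rotation), np.eye(3), atol=0.05)

    def test_planted_rotation_is_undone(self):
        pts = elliptical_cloud(3000, axes=(1.0, 5.0, 0.2), seed=6)
        ang = np.radians(30)
        Rz = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        aligned_t, frame = align_dendrite(cloud_tree(pts @ Rz.T))
        out = aligned_t.coords()[1]
        cov = np.cov((out - out.mean(axis=0)).T)
        off = cov - np.diag(np.diag(cov))
        assert np.all(np.abs(off) < 0.05 * np.max(np.diag(cov)))
        # y must carry the planted long axis
        assert np.argmax(np.diag(cov)) == 1

    def test_idempotent(self):
        pts = elliptical_cloud(400, seed=7)
        t1, _ = align_dendrite(cloud_tree(pts))
        t2, frame2 = align_dendrite(t1)
        assert np.allclose(frame2.rotation, np.eye(3), atol=1e-2)
        assert np.allclose(t1.coords()[1], t2.coords()[1], atol=0.2)

    def test_rotation_is_proper(self):
        for seed in range(5):
            _, frame = align_dendrite(cloud_tree(elliptical_cloud(200, seed=seed)))
            assert np.allclose(frame.rotation @ frame.rotation.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(frame.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_centred_on_root(self):
        pts = elliptical_cloud(100, seed=8) + 50.0
        t = cloud_tree(pts, root_at_origin=False)
        aligned, _ = align_dendrite(t)
        assert np.allclose(aligned.pos(t.root), 0.0, atol=1e-12)


class TestScaling:
    def test_unit_variance_defining_property(self):
        t = cloud_tree(elliptical_cloud(300, seed=9))
        s = scale_dendrite(t, "unit_variance")
        assert np.allclose(s.coords()[1].var(axis=0), 1.0, atol=1e-9)

    def test_population_sd_arithmetic(self):
        t = cloud_tree(elliptical_cloud(50, seed=10))
        s = scale_dendrite(t, "population_sd", {"mu": 4.0, "sigma": 1.0})
        root_p = t.pos(t.root)
        expected = (t.coords()[1] - root_p) / 7.0
        assert np.allclose(s.coords()[1], expected)

    def test_topology_untouched(self):
        t = cloud_tree(elliptical_cloud(60, seed=11))
        s = scale_dendrite(t, "unit_variance")
        assert set(s.edges) == set(t.edges)

    def test_zero_variance_axis_rejected(self):
        pts = elliptical_cloud(50, seed=12)
        pts[:, 2] = 0.0
        with pytest.raises(ValueError, match="zero variance"):
            scale_dendrite(cloud_tree(pts), "unit_variance")


class TestVarianceExplained:
    def test_collinear_is_rank_one(self):
        frame = AlignmentFrame(np.eye(3), np.zeros(3), np.array([5.0, 0.0, 0.0]),
                               np.eye(3))
        assert np.allclose(variance_explained(frame), [1, 0, 0])

    def test_isotropic_thirds(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(100000, 3))
        vals = np.sort(np.linalg.eigvalsh(np.cov(pts.T)))[::-1]
        frame = AlignmentFrame(np.eye(3), np.zeros(3), vals, np.eye(3))
        assert np.allclose(variance_explained(frame), 1 / 3, atol=0.02)

    def test_fractions_non_increasing_and_sum_one(self):
        _, frame = align_dendrite(cloud_tree(elliptical_cloud(200, seed=14)))
        ve = variance_explained(frame)
        assert ve.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(ve) <= 1e-12)


class TestAlignPopulation:
    def _cap_population(self, seed=0, dorsal_dir=None):
        rng = np.random.default_rng(seed)
        pts_by = {}
        R = 100.0
        for i in range(40):
            # cap around +z, elongated along y
            u = rng.normal(0, 0.25)
            v = rng.normal(0, 0.12)
            w = np.array([np.sin(v), np.sin(u), 1.0])
            w /= np.linalg.norm(w)
            center = R * w
            pts_by[i] = center + rng.normal(0, 1.0, size=(30, 3))
        return pts_by

    def test_dorsal_maps_to_positive_y(self):
        pts_by = self._cap_population(seed=1)
        pooled = np.vstack(list(pts_by.values()))
        top = pooled[np.argmax(pooled[:, 1])]
        bottom = pooled[np.argmin(pooled[:, 1])]
        east = pooled[np.argmax(pooled[:, 0])]
        west = pooled[np.argmin(pooled[:, 0])]
        anchors = {"dorsal": top, "ventral": bottom, "anterior": east,
                   "posterior": west}
        aligned, frame = align_population(pts_by, anchors)
        assert frame.apply(top)[1] > 0
        assert frame.apply(east)[0] > 0
        out = np.vstack(list(aligned.values()))
        var = out.var(axis=0)
        assert var[1] > var[0] > var[2]  # DV > AP > depth

    def test_rigidity_preserves_distances(self):
        pts_by = self._cap_population(seed=2)
        pooled = np.vstack(list(pts_by.values()))
        anchors = {
            "dorsal": pooled[np.argmax(pooled[:, 1])],
            "ventral": pooled[np.argmin(pooled[:, 1])],
            "anterior": pooled[np.argmax(pooled[:, 0])],
            "posterior": pooled[np.argmin(pooled[:, 0])],
        }
        aligned, _ = align_population(pts_by, anchors)
        a = pts_by[0] - pts_by[0][0]
        b = aligned[0] - aligned[0][0]
        d_a = np.linalg.norm(a[1:] - a[:-1], axis=1)
        d_b = np.linalg.norm(b[1:] - b[:-1], axis=1)
        assert np.allclose(d_a, d_b, rtol=1e-9)


class TestRotationHelper:
    def test_sign_flip_keeps_proper_rotation(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            m = rng.normal(size=(3, 3))
            cov = m @ m.T
            _, vecs = np.linalg.eigh(cov)
            R = _rotation_from_eigvecs(vecs[:, ::-1])
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)

    def test_pc1_axis_angle_range(self):
        _, frame = align_dendrite(cloud_tree(elliptical_cloud(100, seed=16)))
        assert 0.0 <= pc1_axis_angle(frame) <= 90.0
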