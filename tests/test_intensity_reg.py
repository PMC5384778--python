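"""Intensity-driven registration: linear recovery, FFD machinery, reports."""

import numpy as np
import pytest

from dosewarp import (GeometryError, Image3D, RegistrationConfig,
                      evaluate_registration, finite_diff_gradient, make_phantom,
                      register_ffd, register_linear)
from dosewarp.intensity_reg import FFDObjective, gaussian_pyramid
from dosewarp.transforms import (CompositeTransform, displacement_field,
                                 identity_transform, make_lattice_covering)


@pytest.fixture(scope="module")
def clean_phantom():
    return make_phantom(17, size=32, spacing=3.0, global_motion="none",
                        local_amplitude=0.0, roi_amplitude=0.0, n_impulses=0)


def _center(img):
    lo, hi = img.world_bounds()
    return (lo + hi) / 2


class TestLinearRegistration:
    def test_self_registration_is_identity(self, clean_phantom):
        tgt = clean_phantom.target
        T = register_linear(tgt, tgt, "rigid", RegistrationConfig(max_iter=10))
        c = _center(tgt)
        assert np.linalg.norm(T.apply(c) - c) < 0.1

    def test_recovers_translation(self, clean_phantom):
        tgt = clean_phantom.target
        d = np.array([6.0, 0.0, 0.0])
        src = Image3D(tgt.voxels.copy(), tgt.origin + d, tgt.spacing)
        T = register_linear(tgt, src, "rigid", RegistrationConfig(max_iter=30))
        c = _center(tgt)
        np.testing.assert_allclose(T.apply(c) - c, d, atol=0.5)

    def test_recovers_affine_scale(self):
        # isotropically structured image: random Gaussian blobs
        r = np.random.default_rng(7)
        n, sp = 32, 3.0
        grid = Image3D(np.zeros((n, n, n)), [-(n - 1) * sp / 2] * 3, [sp] * 3)
        pts = grid.grid_world_coords()
        vol = np.zeros((n, n, n))
        for _ in range(25):
            c = r.uniform(-35, 35, 3)
            vol += r.uniform(50, 300) * np.exp(
                -np.sum((pts - c) ** 2, axis=-1) / (2 * r.uniform(6, 15) ** 2))
        tgt = grid.copy(voxels=vol)
        c = _center(tgt)
        scale = 1.05
        src = Image3D(tgt.voxels.copy(), c + scale * (tgt.origin - c),
                      tgt.spacing * scale)
        T = register_linear(tgt, src, "affine", RegistrationConfig(max_iter=40))
        np.testing.assert_allclose(np.diag(T.global_transform.matrix),
                                   [scale] * 3, atol=0.01)

    def test_final_metric_not_below_initial(self, clean_phantom):
        tgt = clean_phantom.target
        src = Image3D(tgt.voxels.copy(), tgt.origin + [4.0, -3.0, 2.0], tgt.spacing)
        hist = []
        register_linear(tgt, src, "rigid", RegistrationConfig(max_iter=15),
                        history_out=hist)
        for _, h in hist:
            objs = [v for _, v in h]
            assert objs[-1] >= objs[0]

    def test_oblique_volumes_rejected(self, clean_phantom, rng):
        from conftest import random_direction_matrix

        tgt = clean_phantom.target
        oblique = Image3D(tgt.voxels.copy(), tgt.origin, tgt.spacing,
                          direction=random_direction_matrix(rng))
        with pytest.raises(GeometryError):
            register_linear(tgt, oblique, "rigid")


class TestFFDObjectiveGradient:
    def test_local_support_gradient_equals_full_recompute(self, rng):
        # small smooth image pair so the naive full finite difference is feasible
        n = 20
        grid = Image3D(np.zeros((n, n, n)), [0, 0, 0], [3.0] * 3)
        pts = grid.grid_world_coords()
        tgt = grid.copy(voxels=(np.sin(pts[..., 0] / 7.0)
                                + np.cos(pts[..., 1] / 9.0)
                                + 0.5 * np.sin(pts[..., 2] / 5.0)))
        src = grid.copy(voxels=np.roll(tgt.voxels, 2, axis=0) + 0.01 * rng.normal(size=(n, n, n)))
        lat = make_lattice_covering(*grid.world_bounds(), 25.0)
        lat.coefficients = rng.normal(size=lat.shape + (3,)) * 0.5
        # restrict to a random subset of free nodes to keep the oracle cheap
        free = np.zeros(lat.shape, dtype=bool)
        flat_idx = rng.choice(np.prod(lat.shape), size=30, replace=False)
        free.ravel()[flat_idx] = True
        lat.free_mask = free
        obj = FFDObjective(tgt, src, lat, identity_transform(), bins=16)
        params = lat.coefficients.ravel().copy()
        h = 0.5
        fast = obj.gradient(params, h)
        free3 = np.repeat(free.ravel(), 3)
        slow = finite_diff_gradient(obj, params, h, free_mask=free3)
        np.testing.assert_allclose(fast[free3], slow[free3], atol=1e-10)
        assert np.all(fast[~free3] == 0.0)

    def test_pyramid_geometry(self, clean_phantom):
        levels = gaussian_pyramid(clean_phantom.target, 3)
        assert [im.shape[0] for im in levels] == [8, 16, 32]
        np.testing.assert_allclose(levels[0].spacing, [12.0] * 3)
        np.testing.assert_allclose(levels[0].origin, clean_phantom.target.origin)


class TestFFDRegistration:
    def test_self_registration_small_displacement(self, clean_phantom):
        tgt = clean_phantom.target
        cfg = RegistrationConfig(max_iter=4, pyramid_levels=2, control_spacing0=24.0)
        T = register_ffd(tgt, tgt, cfg)
        field = displacement_field(T, tgt)
        mean_vox = np.linalg.norm(field, axis=-1).mean() / tgt.spacing.min()
        assert mean_vox < 0.2

    def test_objective_trace_monotone_and_displacement_bounded(self):
        ph = make_phantom(21, size=32, spacing=3.0, global_motion="none",
                          local_amplitude=4.0, roi_amplitude=0.0, n_impulses=0)
        hist = []
        cfg = RegistrationConfig(max_iter=5, pyramid_levels=2, control_spacing0=24.0)
        T = register_ffd(ph.target, ph.source, cfg, history_out=hist)
        n_accepted = 0
        for _, h in hist:
            objs = [v for _, v in h]
            assert all(b >= a for a, b in zip(objs, objs[1:]))
            n_accepted += len(objs) - 1
        # one accepted step moves every coefficient by at most the step length
        field = displacement_field(T, ph.target)
        max_step = 0.4 * 24.0
        assert np.linalg.norm(field, axis=-1).max() <= n_accepted * max_step
        report = evaluate_registration(ph.target, ph.target, transform=T)
        assert np.isfinite(report["jacobian_min"])


class TestEvaluateRegistration:
    def test_perfect_warp(self, clean_phantom):
        tgt = clean_phantom.target
        labs = clean_phantom.labels_target
        rep = evaluate_registration(tgt, tgt, labs, labs)
        assert rep["cc"] == pytest.approx(1.0, abs=1e-12)
        assert rep["nmi"] == pytest.approx(2.0, abs=1e-12)
        assert all(v == 1.0 for v in rep["dice"].values())
        assert len(rep["dice"]) >= 5

    def test_anticorrelated_images(self, clean_phantom):
        tgt = clean_phantom.target
        neg = tgt.copy(voxels=-tgt.voxels)
        rep = evaluate_registration(tgt, neg)
        assert rep["cc"] == pytest.approx(-1.0, abs=1e-12)

    def test_report_matches_standalone_metrics(self, clean_phantom):
        from dosewarp import correlation, nmi

        tgt = clean_phantom.target
        other = tgt.copy(voxels=np.roll(tgt.voxels, 1, axis=2))
        rep = evaluate_registration(tgt, other)
        assert rep["cc"] == correlation(tgt, other)
        assert rep["nmi"] == nmi(tgt, other, bins=64)

    def test_grid_mismatch_rejected(self, clean_phantom):
        tgt = clean_phantom.target
        shifted = Image3D(tgt.voxels.copy(), tgt.origin + 1.0, tgt.spacing)
        with pytest.raises(GeometryError):
            evaluate_registration(tgt, shifted)


def test_multiphase_with_trivial_landmarks_matches_plain_ffd():
    # Q = P and zero-amplitude ROI: the landmark phase fits zero coefficients,
    # so the multiphase result must equal plain FFD in the dense field
    from dosewarp import register_multiphase
    from dosewarp.imagecore import LandmarkSet

    ph = make_phantom(31, size=32, spacing=3.0, global_motion="none",
                      local_amplitude=3.0, roi_amplitude=0.0, n_impulses=0)
    cfg = RegistrationConfig(max_iter=3, pyramid_levels=2, control_spacing0=24.0)
    P = ph.landmarks_target
    Q = LandmarkSet(list(P.names), P.points.copy())
    T_multi = register_multiphase(ph.target, ph.source, ph.roi, P, Q,
                                  cfg_lffd=RegistrationConfig(control_spacing0=40.0,
                                                              pyramid_levels=1),
                                  cfg_ffd=cfg)
    T_ffd = register_ffd(ph.target, ph.source, cfg)
    f1 = displacement_field(T_multi, ph.target)
    f2 = displacement_field(T_ffd, ph.target)
    np.testing.assert_allclose(f1, f2, atol=1e-6)
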