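"""B-spline basis, FFD lattices, composition, warping, serialization."""

import numpy as np
import pytest

from dosewarp import (AffineTransform, CompositeTransform, FFDLattice, Image3D,
                      ROIBox, RigidTransform, apply_transform_point,
                      bspline_basis, ffd_displacement, identity_transform,
                      make_lattice_covering, read_transform,
                      resample_to_reference, subdivide_lattice, warp_image,
                      warp_labels, write_transform)
from dosewarp.errors import ValidationError
from dosewarp.imagecore import voxel_to_world
from dosewarp.transforms import (displacement_field, free_mask_from_roi,
                                 read_displacement_field,
                                 write_displacement_field)

from conftest import random_direction_matrix


def _basis_oracle(l, t):
    """Independent evaluation of the published cubic polynomial pieces."""
    return [
        lambda u: (1 - u) ** 3 / 6,
        lambda u: (3 * u**3 - 6 * u**2 + 4) / 6,
        lambda u: (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6,
        lambda u: u**3 / 6,
    ][l](t)


def _ffd_oracle(lat, p):
    """Naive 4x4x4 triple-loop tensor sum, written independently."""
    g = (np.asarray(p, float) - lat.grid_origin) / lat.spacing
    cell = np.floor(g).astype(int)
    t = g - cell
    disp = np.zeros(3)
    for l in range(4):
        for m in range(4):
            for n in range(4):
                idx = (cell[0] - 1 + l, cell[1] - 1 + m, cell[2] - 1 + n)
                if any(i < 0 or i >= lat.shape[a] for a, i in enumerate(idx)):
                    continue
                w = _basis_oracle(l, t[0]) * _basis_oracle(m, t[1]) * _basis_oracle(n, t[2])
                disp += w * lat.coefficients[idx]
    if lat.strict_piecewise and lat.roi is not None and not lat.roi.contains(p)[0]:
        return np.zeros(3)
    return disp


def _random_lattice(rng, shape=(6, 6, 6), roi=None, strict=False):
    lat = FFDLattice(rng.uniform(-30, -20, 3), rng.uniform(8, 14, 3), shape,
                     roi=roi, strict_piecewise=strict)
    lat.coefficients = rng.normal(size=lat.shape + (3,)) * 3.0
    return lat


class TestBasis:
    def test_values_at_knot(self):
        assert [bspline_basis(l, 0.0) for l in range(4)] == \
            pytest.approx([1 / 6, 2 / 3, 1 / 6, 0.0], abs=1e-15)

    def test_partition_of_unity(self, rng):
        for t in rng.uniform(0, 1, 200):
            assert abs(sum(bspline_basis(l, t) for l in range(4)) - 1.0) < 1e-12

    def test_matches_polynomial_pieces_at_half(self):
        for l in range(4):
            assert bspline_basis(l, 0.5) == pytest.approx(_basis_oracle(l, 0.5), abs=1e-15)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            bspline_basis(4, 0.2)


class TestFFDDisplacement:
    def test_zero_coefficients(self, rng):
        lat = FFDLattice([0, 0, 0], [10, 10, 10], (5, 5, 5))
        pts = rng.uniform(0, 40, size=(20, 3))
        np.testing.assert_array_equal(ffd_displacement(lat, pts), np.zeros((20, 3)))

    def test_single_node_center_weight(self):
        # querying exactly at a displaced node: weight B1(0)^3 = (2/3)^3
        lat = FFDLattice([0, 0, 0], [10, 10, 10], (6, 6, 6))
        d = np.array([5.0, -2.0, 1.0])
        lat.coefficients[3, 3, 3] = d
        node = np.array([30.0, 30.0, 30.0])
        np.testing.assert_allclose(ffd_displacement(lat, node), (2 / 3) ** 3 * d,
                                   atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        lat = _random_lattice(rng)
        lo = lat.grid_origin + lat.spacing
        hi = lat.grid_origin + (np.array(lat.shape) - 2) * lat.spacing
        pts = rng.uniform(lo, hi, size=(100, 3))
        got = ffd_displacement(lat, pts)
        want = np.array([_ffd_oracle(lat, p) for p in pts])
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_constant_coefficients_give_constant_shift(self, rng):
        lat = FFDLattice([0, 0, 0], [10, 10, 10], (8, 8, 8))
        c = np.array([2.0, -1.0, 0.5])
        lat.coefficients[...] = c
        pts = rng.uniform(12, 48, size=(50, 3))  # interior: full support
        np.testing.assert_allclose(ffd_displacement(lat, pts),
                                   np.tile(c, (50, 1)), atol=1e-10)

    def test_strict_piecewise_zero_outside_roi(self, rng):
        roi = ROIBox([10, 10, 10], [40, 40, 40])
        lat = make_lattice_covering([0, 0, 0], [60, 60, 60], 10.0, roi=roi,
                                    strict_piecewise=True)
        lat.coefficients = rng.normal(size=lat.shape + (3,)) * 3.0
        inside = rng.uniform(11, 39, size=(10, 3))
        outside = np.array([[50.0, 50.0, 50.0], [0.0, 20.0, 20.0]])
        assert np.all(np.linalg.norm(ffd_displacement(lat, inside), axis=1) > 0)
        np.testing.assert_array_equal(ffd_displacement(lat, outside), np.zeros((2, 3)))

    def test_smooth_mode_decays_to_zero_beyond_two_spacings(self):
        roi = ROIBox([40, 40, 40], [60, 60, 60])
        lat = make_lattice_covering([0, 0, 0], [100, 100, 100], 10.0, roi=roi)
        lat.coefficients[lat.free_mask] = 5.0
        far = np.array([[5.0, 5.0, 5.0], [95.0, 95.0, 5.0], [5.0, 50.0, 95.0]])
        # > 2 control spacings from any free node
        free_nodes = lat.node_positions()[lat.free_mask]
        for p in far:
            assert np.min(np.abs(free_nodes - p).max(axis=1)) > 2 * lat.spacing.max()
        np.testing.assert_array_equal(ffd_displacement(lat, far), np.zeros((3, 3)))


class TestComposite:
    def test_identity(self, rng):
        p = rng.normal(size=3)
        np.testing.assert_array_equal(apply_transform_point(identity_transform(), p), p)

    def test_pure_translation(self, rng):
        t = np.array([1.0, -2.0, 3.0])
        T = CompositeTransform(RigidTransform(np.eye(3), t), [])
        p = rng.normal(size=(5, 3))
        np.testing.assert_allclose(apply_transform_point(T, p), p + t)

    def test_rigid_plus_lattice_is_sum_of_parts(self, rng):
        g = RigidTransform(random_direction_matrix(rng), rng.normal(size=3))
        lat = _random_lattice(rng)
        T = CompositeTransform(g, [lat])
        pts = rng.uniform(-10, 30, size=(20, 3))
        want = g.apply(pts) + ffd_displacement(lat, pts)
        np.testing.assert_allclose(T.apply(pts), want, atol=1e-12)

    def test_transform_invariants(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), [0, 0, 0])  # reflection
        with pytest.raises(ValidationError):
            AffineTransform(np.zeros((3, 3)), [0, 0, 0])  # singular


class TestWarp:
    def _ramp_image(self):
        vol = np.add.outer(np.add.outer(np.arange(12.0), 0.5 * np.arange(12.0)),
                           0.25 * np.arange(12.0))
        return Image3D(vol, [0, 0, 0], [2, 2, 2])

    def test_identity_equals_resample(self, rng):
        src = Image3D(rng.normal(size=(8, 8, 8)), [0, 0, 0], [2, 2, 2])
        ref = Image3D(np.zeros((6, 6, 6)), [1, 1, 1], [2, 2, 2])
        a = warp_image(src, identity_transform(), ref)
        b = resample_to_reference(src, ref, "linear")
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_integer_voxel_shift(self, rng):
        src = Image3D(rng.normal(size=(8, 8, 8)), [0, 0, 0], [2, 2, 2])
        T = CompositeTransform(RigidTransform(np.eye(3), [2.0, 0.0, 0.0]), [])
        out = warp_image(src, T, src)
        np.testing.assert_allclose(out.voxels[:7], src.voxels[1:], atol=1e-12)

    def test_ffd_warp_matches_pointwise_oracle(self, rng):
        src = self._ramp_image()
        lat = _random_lattice(rng, shape=(7, 7, 7))
        lat.grid_origin = np.array([-20.0, -20.0, -20.0])
        lat.spacing = np.array([10.0, 10.0, 10.0])
        T = CompositeTransform(None, [lat])
        out = warp_image(src, T, src, interp="linear", pad_value=-5.0)
        for _ in range(50):
            idx = tuple(rng.integers(0, 12, size=3))
            p = voxel_to_world(src, idx)
            q = (p + _ffd_oracle(lat, p) - src.origin) / src.spacing
            if np.all((q >= 0) & (q <= 11)):
                c = np.floor(q).astype(int)
                c = np.minimum(c, 10)
                f = q - c
                val = 0.0
                for dx in (0, 1):
                    for dy in (0, 1):
                        for dz in (0, 1):
                            w = ((f[0] if dx else 1 - f[0])
                                 * (f[1] if dy else 1 - f[1])
                                 * (f[2] if dz else 1 - f[2]))
                            val += w * src.voxels[c[0] + dx, c[1] + dy, c[2] + dz]
            else:
                val = -5.0
            assert out.voxels[idx] == pytest.approx(val, abs=1e-8)

    def test_label_warp_identity_and_closure(self, rng):
        lab = Image3D(rng.integers(0, 4, size=(8, 8, 8)).astype(np.int32),
                      [0, 0, 0], [1, 1, 1])
        same = warp_labels(lab, identity_transform(), lab)
        np.testing.assert_array_equal(same.voxels, lab.voxels)
        T = CompositeTransform(RigidTransform(np.eye(3), [0.5, 0.5, 0.5]), [])
        shifted = warp_labels(lab, T, lab)
        assert set(np.unique(shifted.voxels)) <= set(np.unique(lab.voxels)) | {0}

    def test_label_warp_dice_against_analytic_truth(self):
        n, sp = 32, 2.0
        grid = Image3D(np.zeros((n, n, n)), [0, 0, 0], [sp] * 3)
        pts = grid.grid_world_coords().reshape(-1, 3)
        center = np.array([32.0, 32.0, 32.0])
        shift = np.array([5.0, -3.0, 2.0])
        src_lab = (np.linalg.norm(pts - center, axis=1) <= 22.0).astype(np.int32)
        src = grid.copy(voxels=src_lab.reshape(grid.shape))
        T = CompositeTransform(RigidTransform(np.eye(3), shift), [])
        warped = warp_labels(src, T, grid)
        truth = (np.linalg.norm(pts + shift - center, axis=1) <= 22.0)
        got = warped.voxels.reshape(-1) == 1
        dice = 2 * np.sum(truth & got) / (truth.sum() + got.sum())
        assert dice > 0.95

    def test_non_integer_labels_rejected(self):
        lab = Image3D(np.full((4, 4, 4), 0.5), [0, 0, 0], [1, 1, 1])
        with pytest.raises(ValidationError):
            warp_labels(lab, identity_transform(), lab)


class TestSerialization:
    def test_identity_round_trip(self, tmp_path):
        path = str(tmp_path / "t.tfm.json")
        write_transform(identity_transform(), path)
        back = read_transform(path)
        assert back.global_transform is None and back.locals_ == []

    def test_random_composite_round_trip(self, tmp_path, rng):
        roi = ROIBox([0, 0, 0], [30, 30, 30])
        lat1 = _random_lattice(rng)
        lat2 = _random_lattice(rng, roi=roi, strict=True)
        lat2.free_mask = free_mask_from_roi(lat2, roi)
        T = CompositeTransform(
            RigidTransform(random_direction_matrix(rng), rng.normal(size=3)),
            [lat1, lat2],
        )
        path = str(tmp_path / "t.tfm.json")
        write_transform(T, path)
        back = read_transform(path)
        for a, b in zip(T.locals_, back.locals_):
            np.testing.assert_array_equal(a.coefficients, b.coefficients)
            np.testing.assert_array_equal(a.free_mask, b.free_mask)
            assert a.strict_piecewise == b.strict_piecewise
        pts = rng.uniform(-20, 50, size=(100, 3))
        np.testing.assert_allclose(back.apply(pts), T.apply(pts), atol=1e-12)

    def test_schema_violation_names_field(self, tmp_path):
        path = tmp_path / "bad.tfm.json"
        path.write_text('{"global": {"type": "identity", "matrix": []}}')
        with pytest.raises(Exception, match="lattices"):
            read_transform(str(path))

    def test_dense_field_matches_analytic(self, tmp_path, rng):
        lat = _random_lattice(rng)
        T = CompositeTransform(None, [lat])
        ref = Image3D(np.zeros((6, 6, 6)), [-10, -10, -10], [8, 8, 8])
        path = str(tmp_path / "field.nii.gz")
        write_displacement_field(T, ref, path)
        field = read_displacement_field(path)
        idx = (2, 3, 4)
        p = voxel_to_world(ref, idx)
        np.testing.assert_allclose(field[idx], ffd_displacement(lat, p), atol=1e-10)


class TestSubdivision:
    def test_displacement_preserved(self, rng):
        lat = _random_lattice(rng, shape=(7, 6, 8))
        fine = subdivide_lattice(lat)
        np.testing.assert_allclose(fine.spacing, lat.spacing / 2)
        pts = rng.uniform(lat.grid_origin - 2 * lat.spacing,
                          lat.grid_origin + (np.array(lat.shape) + 1) * lat.spacing,
                          size=(200, 3))
        np.testing.assert_allclose(ffd_displacement(fine, pts),
                                   ffd_displacement(lat, pts), atol=1e-10)

    def test_displacement_field_of_composite(self, rng):
        lat = _random_lattice(rng)
        ref = Image3D(np.zeros((5, 5, 5)), [0, 0, 0], [10, 10, 10])
        field = displacement_field(CompositeTransform(None, [lat]), ref)
        p = voxel_to_world(ref, (1, 2, 3))
        np.testing.assert_allclose(field[1, 2, 3], ffd_displacement(lat, p), atol=1e-12)
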