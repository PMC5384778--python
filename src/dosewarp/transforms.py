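"""Spatial transform family: rigid, affine, B-spline FFD lattices, composites.

The total transform is *additive*: ``T(x) = T_global(x) + sum_k u_k(x)`` where
``T_global`` is rigid or affine and each ``u_k`` is the displacement field of a
free-form-deformation (FFD) lattice evaluated at the target-frame point ``x``.
Image warping uses the pull-back convention: the transform maps target-frame
coordinates into the source frame, and the warped image is the source sampled
at ``T(world(i))`` for every target voxel ``i``.

A lattice is an ``(n_x, n_y, n_z)`` mesh of control points with uniform world
spacing ``delta``; the displacement at a point is the tensor-product cubic
B-spline sum over its 4x4x4 control-point neighbourhood.  Coefficients are
world-space displacements in mm.  Control points outside the stored mesh
contribute zero (virtual zero padding), so the field decays smoothly to zero
away from the displaced region.

With ``strict_piecewise=True`` and an ROI set, the lattice instead reproduces
the literal piecewise definition used for landmark-driven registration: the
spline sum inside the ROI and the zero vector outside it.  The default smooth
mode evaluates the spline everywhere, which keeps the field continuous at the
ROI boundary while still vanishing away from the free control points.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field

import numpy as np

from ._interp import sample_at_index
from .errors import ParseError, ValidationError
from .imagecore import Image3D, ROIBox, world_to_voxel

__all__ = [
    "bspline_basis",
    "bspline_basis_vector",
    "RigidTransform",
    "AffineTransform",
    "FFDLattice",
    "CompositeTransform",
    "identity_transform",
    "make_lattice_covering",
    "free_mask_from_roi",
    "subdivide_lattice",
    "ffd_displacement",
    "apply_transform_point",
    "warp_image",
    "warp_labels",
    "read_transform",
    "write_transform",
    "displacement_field",
    "write_displacement_field",
    "read_displacement_field",
]


# ---------------------------------------------------------------------------
# uniform cubic B-spline basis
# ---------------------------------------------------------------------------

def bspline_basis(l: int, t: float) -> float:
    """Uniform cubic B-spline basis ``B_l(t)`` for ``l`` in 0..3, ``t`` in [0, 1).

    The four pieces form a partition of unity: ``sum_l B_l(t) == 1``.
    """
    if l not in (0, 1, 2, 3):
        raise ValueError(f"basis index must be 0..3, got {l}")
    t = float(t)
    if l == 0:
        return (1.0 - t) ** 3 / 6.0
    if l == 1:
        return (3.0 * t**3 - 6.0 * t**2 + 4.0) / 6.0
    if l == 2:
        return (-3.0 * t**3 + 3.0 * t**2 + 3.0 * t + 1.0) / 6.0
    return t**3 / 6.0


def bspline_basis_vector(t: np.ndarray) -> np.ndarray:
    """All four basis values for fractions ``t``; shape ``(N, 4)``."""
    t = np.asarray(t, dtype=float)
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1.0 - t) ** 3 / 6.0,
            (3.0 * t3 - 6.0 * t2 + 4.0) / 6.0,
            (-3.0 * t3 + 3.0 * t2 + 3.0 * t + 1.0) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# global transforms
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValidationError("rigid rotation must be orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValidationError("rigid rotation must be proper (det = +1)")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    @property
    def matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class AffineTransform:
    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValidationError("affine matrix must be invertible")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix.T + self.translation

    @property
    def matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.matrix
        m[:3, 3] = self.translation
        return m


# ---------------------------------------------------------------------------
# FFD lattice
# ---------------------------------------------------------------------------

@dataclass
class FFDLattice:
    """B-spline control-point lattice holding world-mm displacements."""

    grid_origin: np.ndarray
    spacing: np.ndarray
    shape: tuple[int, int, int]
    coefficients: np.ndarray = None  # type: ignore[assignment]
    free_mask: np.ndarray = None  # type: ignore[assignment]
    roi: ROIBox | None = None
    strict_piecewise: bool = False

    def __post_init__(self) -> None:
        self.grid_origin = np.asarray(self.grid_origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.shape = tuple(int(n) for n in self.shape)
        if any(n < 4 for n in self.shape):
            raise ValidationError(f"lattice needs >= 4 control points per axis, got {self.shape}")
        if not np.all(self.spacing > 0):
            raise ValidationError("lattice spacing must be strictly positive")
        if self.coefficients is None:
            self.coefficients = np.zeros(self.shape + (3,))
        self.coefficients = np.asarray(self.coefficients, dtype=float).reshape(self.shape + (3,))
        if not np.all(np.isfinite(self.coefficients)):
            raise ValidationError("lattice coefficients must be finite")
        if self.free_mask is None:
            self.free_mask = np.ones(self.shape, dtype=bool)
        self.free_mask = np.asarray(self.free_mask, dtype=bool).reshape(self.shape)

    @property
    def n_free(self) -> int:
        return int(self.free_mask.sum())

    def node_positions(self) -> np.ndarray:
        """World positions of all control points, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n, dtype=float) for n in self.shape), indexing="ij"),
            axis=-1,
        )
        return self.grid_origin + idx * self.spacing

    def covers(self, pts: np.ndarray) -> np.ndarray:
        """True where a point has its full 4x4x4 neighbourhood inside the mesh."""
        g = (np.atleast_2d(np.asarray(pts, float)) - self.grid_origin) / self.spacing
        cell = np.floor(g).astype(int)
        n = np.array(self.shape)
        return np.all((cell - 1 >= 0) & (cell + 2 <= n - 1), axis=1)

    def basis_weights(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-point base control index ``cell-1`` and the (N,3,4) weight table."""
        g = (np.atleast_2d(np.asarray(pts, float)) - self.grid_origin) / self.spacing
        cell = np.floor(g).astype(int)
        t = g - cell
        w = np.stack([bspline_basis_vector(t[:, a]) for a in range(3)], axis=1)
        return cell - 1, w

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        return ffd_displacement(self, pts)

    def copy(self) -> "FFDLattice":
        return FFDLattice(
            self.grid_origin.copy(), self.spacing.copy(), self.shape,
            self.coefficients.copy(), self.free_mask.copy(), self.roi,
            self.strict_piecewise,
        )


def ffd_displacement(lat: FFDLattice, pts: np.ndarray) -> np.ndarray:
    """Tensor-product B-spline displacement of ``lat`` at world points (mm).

    Control points outside the stored mesh contribute zero.  In strict
    piecewise mode the displacement is the spline sum inside the ROI and the
    zero vector outside it.
    """
    pts = np.asarray(pts, dtype=float)
    single = pts.ndim == 1
    pts2 = np.atleast_2d(pts)
    base, w = lat.basis_weights(pts2)
    disp = np.zeros((pts2.shape[0], 3))
    n = lat.shape
    C = lat.coefficients
    for l in range(4):
        ix = base[:, 0] + l
        okx = (ix >= 0) & (ix < n[0])
        wl = w[:, 0, l]
        for m in range(4):
            iy = base[:, 1] + m
            okxy = okx & (iy >= 0) & (iy < n[1])
            wlm = wl * w[:, 1, m]
            for q in range(4):
                iz = base[:, 2] + q
                ok = okxy & (iz >= 0) & (iz < n[2])
                if not ok.any():
                    continue
                wt = (wlm * w[:, 2, q])[ok]
                disp[ok] += wt[:, None] * C[ix[ok], iy[ok], iz[ok]]
    if lat.strict_piecewise and lat.roi is not None:
        disp[~lat.roi.contains(pts2)] = 0.0
    return disp[0] if single else disp


def make_lattice_covering(lower, upper, spacing, roi: ROIBox | None = None,
                          strict_piecewise: bool = False) -> FFDLattice:
    """Lattice covering the world box ``[lower, upper]`` plus a one-spacing margin.

    The mesh is sized so that every point of the box (and the margin) has a
    complete 4x4x4 support neighbourhood.
    """
    lower = np.asarray(lower, dtype=float).reshape(3)
    upper = np.asarray(upper, dtype=float).reshape(3)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if not np.all(upper > lower):
        raise ValidationError("domain upper bound must exceed lower bound")
    shape = tuple(int(np.ceil((upper[a] - lower[a]) / spacing[a])) + 5 for a in range(3))
    origin = lower - 2.0 * spacing
    lat = FFDLattice(origin, spacing, shape, roi=roi, strict_piecewise=strict_piecewise)
    if roi is not None:
        lat.free_mask = free_mask_from_roi(lat, roi)
    return lat


def free_mask_from_roi(lat: FFDLattice, roi: ROIBox) -> np.ndarray:
    """A control point is free iff its node lies in the ROI dilated by one spacing."""
    nodes = lat.node_positions().reshape(-1, 3)
    return roi.dilated(lat.spacing).contains(nodes).reshape(lat.shape)


def subdivide_lattice(lat: FFDLattice) -> FFDLattice:
    """Halve the control spacing, carrying the displacement field exactly.

    Uses the cubic B-spline two-scale relation with stencils (1,6,1)/8 on even
    and (1,1)/2 on odd fine nodes, so the fine lattice represents the same
    displacement field everywhere.
    """
    taps = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 8.0  # h_{-2..2}
    C = lat.coefficients
    for axis in range(3):
        n = C.shape[axis]
        fine_n = 2 * n + 3
        out_shape = list(C.shape)
        out_shape[axis] = fine_n
        out = np.zeros(out_shape)
        for k in range(-2, 3):
            # fine index j' = 2i + k + 2 for coarse index i
            src = [slice(None)] * C.ndim
            dst = [slice(None)] * C.ndim
            dst[axis] = slice(k + 2, k + 2 + 2 * n, 2)
            out[tuple(dst)] += taps[k + 2] * C[tuple(src)]
        C = out
    new = FFDLattice(
        lat.grid_origin - lat.spacing,
        lat.spacing / 2.0,
        C.shape[:3],
        C,
        roi=lat.roi,
        strict_piecewise=lat.strict_piecewise,
    )
    new.free_mask = (
        free_mask_from_roi(new, lat.roi) if lat.roi is not None
        else np.ones(new.shape, dtype=bool)
    )
    return new


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------

@dataclass
class CompositeTransform:
    """Global (rigid/affine/identity) plus an ordered sum of FFD lattices."""

    global_transform: RigidTransform | AffineTransform | None = None
    locals_: list[FFDLattice] = field(default_factory=list)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        pts2 = np.atleast_2d(pts)
        out = self.global_transform.apply(pts2) if self.global_transform is not None else pts2.copy()
        for lat in self.locals_:
            out = out + ffd_displacement(lat, pts2)
        return out[0] if single else out


def identity_transform() -> CompositeTransform:
    return CompositeTransform(None, [])


def apply_transform_point(T: CompositeTransform, p) -> np.ndarray:
    """``T_global(p) + sum_k u_k(p)`` — the additive global+local model."""
    return T.apply(p)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def sample_at_world(img: Image3D, pts_world: np.ndarray, interp: str, pad: float) -> np.ndarray:
    idx = world_to_voxel(img, pts_world)
    return sample_at_index(img.voxels, idx, interp, pad)


def warp_image(src: Image3D, T: CompositeTransform, ref: Image3D,
               interp: str = "linear", pad_value: float | None = None) -> Image3D:
    """Pull ``src`` back through ``T`` onto the grid of ``ref``.

    ``T`` must map reference-frame world points into the source frame;
    ``out[i] = interp(src, T(world(i)))``.
    """
    if pad_value is None:
        pad_value = float(src.voxels.min())
    pts = ref.grid_world_coords().reshape(-1, 3)
    mapped = T.apply(pts)
    vals = sample_at_world(src, mapped, interp, pad_value)
    return Image3D(vals.reshape(ref.shape), ref.origin.copy(), ref.spacing.copy(),
                   ref.direction.copy(), ref.frame_tag)


def warp_labels(src_labels: Image3D, T: CompositeTransform, ref: Image3D) -> Image3D:
    """Warp an integer label volume with nearest-neighbour interpolation."""
    vox = src_labels.voxels
    if not np.issubdtype(vox.dtype, np.integer) and not np.all(vox == np.round(vox)):
        raise ValidationError("label volume must be integer-valued")
    out = warp_image(src_labels, T, ref, interp="nearest", pad_value=0.0)
    out.voxels = np.round(out.voxels).astype(np.int32)
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _encode(arr: np.ndarray) -> str:
    # x index fastest among the spatial axes, 3 vector components interleaved
    a = np.ascontiguousarray(np.asarray(arr, dtype="<f8").transpose(2, 1, 0, 3))
    return base64.b64encode(a.tobytes()).decode("ascii")


def _decode(text: str, shape) -> np.ndarray:
    raw = base64.b64decode(text.encode("ascii"))
    arr = np.frombuffer(raw, dtype="<f8").reshape(shape[2], shape[1], shape[0], 3)
    return arr.transpose(2, 1, 0, 3).astype(float)


def write_transform(T: CompositeTransform, path: str) -> None:
    g = T.global_transform
    if g is None:
        global_doc = {"type": "identity", "matrix": np.eye(4).tolist()}
    else:
        global_doc = {
            "type": "rigid" if isinstance(g, RigidTransform) else "affine",
            "matrix": g.matrix4.tolist(),
        }
    lattices = []
    for lat in T.locals_:
        mask = np.ascontiguousarray(lat.free_mask.transpose(2, 1, 0).astype(np.uint8))
        lattices.append({
            "origin": lat.grid_origin.tolist(),
            "spacing": lat.spacing.tolist(),
            "shape": list(lat.shape),
            "strict_piecewise": bool(lat.strict_piecewise),
            "roi": None if lat.roi is None else [lat.roi.lower.tolist(), lat.roi.upper.tolist()],
            "coefficients": _encode(lat.coefficients),
            "free_mask": base64.b64encode(mask.tobytes()).decode("ascii"),
        })
    doc = {"format": "dosewarp-transform", "version": 1,
           "global": global_doc, "lattices": lattices}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_transform(path: str) -> CompositeTransform:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path!r}: not valid JSON: {exc}") from exc
    for key in ("global", "lattices"):
        if key not in doc:
            raise ParseError(f"{path!r}: missing required field {key!r}")
    gdoc = doc["global"]
    for key in ("type", "matrix"):
        if key not in gdoc:
            raise ParseError(f"{path!r}: global transform missing field {key!r}")
    m = np.asarray(gdoc["matrix"], dtype=float).reshape(4, 4)
    if gdoc["type"] == "identity":
        g = None
    elif gdoc["type"] == "rigid":
        g = RigidTransform(m[:3, :3], m[:3, 3])
    elif gdoc["type"] == "affine":
        g = AffineTransform(m[:3, :3], m[:3, 3])
    else:
        raise ParseError(f"{path!r}: unknown global transform type {gdoc['type']!r}")
    lats = []
    for i, ldoc in enumerate(doc["lattices"]):
        for key in ("origin", "spacing", "shape", "coefficients"):
            if key not in ldoc:
                raise ParseError(f"{path!r}: lattice {i} missing field {key!r}")
        shape = tuple(int(n) for n in ldoc["shape"])
        roi = None
        if ldoc.get("roi") is not None:
            roi = ROIBox(ldoc["roi"][0], ldoc["roi"][1])
        lat = FFDLattice(
            np.asarray(ldoc["origin"], float),
            np.asarray(ldoc["spacing"], float),
            shape,
            _decode(ldoc["coefficients"], shape),
            roi=roi,
            strict_piecewise=bool(ldoc.get("strict_piecewise", False)),
        )
        if "free_mask" in ldoc:
            raw = base64.b64decode(ldoc["free_mask"].encode("ascii"))
            mask = np.frombuffer(raw, dtype=np.uint8).reshape(shape[2], shape[1], shape[0])
            lat.free_mask = mask.transpose(2, 1, 0).astype(bool)
        lats.append(lat)
    return CompositeTransform(g, lats)


# ---------------------------------------------------------------------------
# dense displacement-field export
# ---------------------------------------------------------------------------

def displacement_field(T: CompositeTransform, ref: Image3D) -> np.ndarray:
    """Dense ``T(x) - x`` (mm, LPS) on the reference grid; shape ``(*shape, 3)``."""
    pts = ref.grid_world_coords().reshape(-1, 3)
    return (T.apply(pts) - pts).reshape(ref.shape + (3,))


def write_displacement_field(T: CompositeTransform, ref: Image3D, path: str) -> None:
    import nibabel as nib

    from .imagecore import _RAS2LPS  # noqa: PLC0415

    field_mm = displacement_field(T, ref)
    affine = np.eye(4)
    affine[:3, :3] = _RAS2LPS @ (ref.direction * ref.spacing)
    affine[:3, 3] = _RAS2LPS @ ref.origin
    nib.save(nib.Nifti1Image(field_mm, affine), path)


def read_displacement_field(path: str) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(path).dataobj)


def jacobian_determinant(T: CompositeTransform, ref: Image3D) -> np.ndarray:
    """Voxelwise determinant of the spatial Jacobian of ``T`` on ``ref``'s grid."""
    mapped = T.apply(ref.grid_world_coords().reshape(-1, 3)).reshape(ref.shape + (3,))
    grads = np.empty(ref.shape + (3, 3))
    for comp in range(3):
        for axis in range(3):
            grads[..., comp, axis] = np.gradient(mapped[..., comp], ref.spacing[axis], axis=axis)
    # differentiation along voxel axes: with an orthonormal direction matrix the
    # determinant equals the world-frame one
    return np.linalg.det(grads)
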