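"""Synthetic pelvic phantom generator with known ground truth.

Emulates the paired-CT setting this package targets: a fixed planning volume
(the registration target), a moving volume acquired in a different session
(the source) related to it by a known global motion plus smooth local
deformation, a large extra deformation confined to a "thigh" region of
interest, applicator-like bright impulse voxels in the source only, organ
labels, corresponding landmarks, and a synthetic dose grid.

Construction is purely analytic: an intensity/label *scene* is defined as a
function of world coordinates (body, pelvic bone ring, bladder, rectum,
tumour, two thigh cylinders with bone cores, plus smooth cosine texture), the
source samples the scene directly, and the target samples the scene at
``T_truth(x)``.  Pulling the source back through ``T_truth`` therefore
reproduces the target without any resampling error, landmark pairs satisfy
``q = T_truth(p)`` exactly, and the local deformation fields are rescaled so
their maximum displacement equals the requested amplitude exactly.

Everything derives from one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .dose import DoseGrid
from .errors import ConfigError, GeometryError
from .imagecore import Image3D, LandmarkSet, ROIBox
from .transforms import (AffineTransform, CompositeTransform, FFDLattice,
                         RigidTransform, ffd_displacement, free_mask_from_roi,
                         make_lattice_covering)

__all__ = ["PhantomTruth", "make_phantom", "make_dose"]

_AIR = -1000.0

# label ids
BODY, PELVIS, BLADDER, RECTUM, TUMOR, THIGH, THIGH_BONE = 1, 2, 3, 4, 5, 6, 7


@dataclass
class PhantomTruth:
    """Everything a parameter-recovery test needs about one phantom."""

    target: Image3D
    source: Image3D
    clean_source: Image3D
    truth_transform: CompositeTransform
    labels_target: Image3D
    labels_source: Image3D
    landmarks_target: LandmarkSet
    landmarks_source: LandmarkSet
    dose_source: DoseGrid
    roi: ROIBox
    seed: int
    tumor_center: np.ndarray
    half_extent: np.ndarray


class _Scene:
    """Analytic intensity and label functions of world position (mm)."""

    def __init__(self, half_extent: np.ndarray, rng: np.random.Generator):
        h = self.h = half_extent
        s = float(min(h))
        self.body_c = np.array([0.0, -0.10 * h[1]])
        self.body_r = np.array([0.75 * h[0], 0.55 * h[1]])
        self.ring_out = np.array([0.45 * h[0], 0.35 * h[1]])
        self.ring_in = np.array([0.30 * h[0], 0.22 * h[1]])
        self.ring_z = 0.60 * h[2]
        self.bladder_c = np.array([0.0, -0.15 * h[1], 0.15 * h[2]])
        self.bladder_r = np.array([0.16 * h[0], 0.13 * h[1], 0.18 * h[2]])
        self.rectum_c = np.array([0.0, -0.42 * h[1], -0.05 * h[2]])
        self.rectum_r = np.array([0.10 * h[0], 0.10 * h[1], 0.35 * h[2]])
        self.tumor_c = np.array([0.0, -0.30 * h[1], 0.02 * h[2]])
        self.tumor_r = np.array([0.09 * h[0], 0.09 * h[1], 0.12 * h[2]])
        self.thigh_x = 0.52 * h[0]
        self.thigh_y = 0.45 * h[1]
        self.thigh_r = 0.20 * s
        self.core_r = 0.07 * s
        self.tube_c = np.array([0.0, -0.15 * h[1]])
        self.tube_r = 0.05 * s
        self.tube_z = 0.80 * h[2]
        # smooth multi-scale texture so intensity registration has gradients
        n_waves = 4
        dirs = rng.normal(size=(n_waves, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        wavelengths = rng.uniform(25.0, 60.0, size=n_waves)
        self._wave_k = dirs * (2.0 * np.pi / wavelengths)[:, None]
        self._wave_phi = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
        self._wave_amp = 15.0

    # -- membership helpers -------------------------------------------------
    def _ellipse2(self, pts, c, r):
        return ((pts[:, 0] - c[0]) / r[0]) ** 2 + ((pts[:, 1] - c[1]) / r[1]) ** 2 <= 1.0

    def _ellipsoid(self, pts, c, r):
        return np.sum(((pts - c) / r) ** 2, axis=1) <= 1.0

    def _thigh(self, pts, sign):
        """Thigh muscle cylinder with a femur-like core: tapered shaft plus a
        'femoral head' sphere, so the structure is not translation-invariant
        along any axis and misregistration is visible to intensity metrics."""
        d2 = (pts[:, 0] - sign * self.thigh_x) ** 2 + (pts[:, 1] - self.thigh_y) ** 2
        outer = d2 <= self.thigh_r**2
        zfrac = pts[:, 2] / self.h[2]
        shaft_r = self.core_r * (1.25 - 0.6 * zfrac)  # tapers toward superior end
        core = d2 <= shaft_r**2
        head_c = np.array([sign * self.thigh_x, self.thigh_y, 0.55 * self.h[2]])
        head = np.sum((pts - head_c) ** 2, axis=1) <= (2.0 * self.core_r) ** 2
        return outer, core | head

    def applicator_tube(self, pts):
        d2 = (pts[:, 0] - self.tube_c[0]) ** 2 + (pts[:, 1] - self.tube_c[1]) ** 2
        return (d2 <= self.tube_r**2) & (np.abs(pts[:, 2]) <= self.tube_z)

    def labels(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        lab = np.zeros(pts.shape[0], dtype=np.int32)
        lab[self._ellipse2(pts, self.body_c, self.body_r)] = BODY
        for sign in (-1.0, 1.0):
            outer, core = self._thigh(pts, sign)
            lab[outer] = THIGH
            lab[core] = THIGH_BONE
        ring = (
            self._ellipse2(pts, self.body_c, self.ring_out)
            & ~self._ellipse2(pts, self.body_c, self.ring_in)
            & (np.abs(pts[:, 2]) <= self.ring_z)
        )
        lab[ring] = PELVIS
        lab[self._ellipsoid(pts, self.bladder_c, self.bladder_r)] = BLADDER
        lab[self._ellipsoid(pts, self.rectum_c, self.rectum_r)] = RECTUM
        lab[self._ellipsoid(pts, self.tumor_c, self.tumor_r)] = TUMOR
        return lab

    def intensity(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        lab = self.labels(pts)
        base = {BODY: 100.0, PELVIS: 1000.0, BLADDER: 160.0, RECTUM: 60.0,
                TUMOR: 140.0, THIGH: 120.0, THIGH_BONE: 800.0}
        out = np.full(pts.shape[0], _AIR)
        for value, level in base.items():
            out[lab == value] = level
        # marrow/muscle intensity drifts along the femur axis
        zfrac = pts[:, 2] / self.h[2]
        out[lab == THIGH_BONE] += 150.0 * zfrac[lab == THIGH_BONE]
        out[lab == THIGH] += 25.0 * zfrac[lab == THIGH]
        texture = np.zeros(pts.shape[0])
        for k, phi in zip(self._wave_k, self._wave_phi):
            texture += np.cos(pts @ k + phi)
        out[lab > 0] += self._wave_amp * texture[lab > 0]
        return out


def _random_local_lattice(rng, lower, upper, spacing, amplitude, grid_pts,
                          roi: ROIBox | None = None) -> FFDLattice | None:
    """Random smooth lattice rescaled so max |u| over the grid == amplitude."""
    if amplitude <= 0:
        return None
    lat = make_lattice_covering(lower, upper, spacing, roi=roi)
    coeff = rng.normal(size=lat.shape + (3,))
    if roi is not None:
        # a coherent push plus variation, confined to the free (ROI) nodes
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coeff = direction + 0.3 * coeff
        coeff[~lat.free_mask] = 0.0
    lat.coefficients = coeff
    disp = ffd_displacement(lat, grid_pts)
    peak = float(np.linalg.norm(disp, axis=1).max())
    if peak == 0.0:
        return None
    lat.coefficients = coeff * (amplitude / peak)
    return lat


def _global_motion(rng, kind: str):
    if kind == "none":
        return None
    angles = rng.uniform(-0.03, 0.03, size=3)
    translation = rng.uniform(-5.0, 5.0, size=3)
    rot = Rotation.from_euler("xyz", angles).as_matrix()
    if kind == "rigid":
        return RigidTransform(rot, translation)
    if kind == "affine":
        mat = rot @ (np.eye(3) + rng.uniform(-0.02, 0.02, size=(3, 3)))
        return AffineTransform(mat, translation)
    raise ConfigError(f"global motion must be 'rigid', 'affine' or 'none', got {kind!r}")


def make_phantom(seed: int, size=64, spacing=2.0, global_motion: str = "rigid",
                 local_amplitude: float = 4.0, roi_amplitude: float = 12.0,
                 n_impulses: int = 150) -> PhantomTruth:
    """Generate one phantom pair with known ground truth.

    Parameters
    ----------
    seed:
        Integer seed; the phantom is bit-reproducible from it.
    size, spacing:
        Voxels per axis (scalar or triple, >= 32) and voxel size in mm.
    global_motion:
        ``rigid`` (default), ``affine``, or ``none`` — the sampled global part
        of the ground-truth transform (rotations up to ~1.7 degrees,
        translations up to 5 mm).
    local_amplitude:
        Peak displacement (mm) of the smooth background deformation
        (40 mm truth lattice).
    roi_amplitude:
        Peak displacement (mm) of the extra deformation confined to the thigh
        ROI (24 mm truth lattice, free nodes inside the dilated ROI only).
    n_impulses:
        Number of bright applicator-like impulse voxels added to the source.
    """
    size = np.broadcast_to(np.asarray(size, dtype=int), (3,)).copy()
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(size < 32):
        raise ConfigError(f"phantom size must be >= 32 voxels per axis, got {size.tolist()}")
    rng = np.random.default_rng(seed)

    half = (size - 1) * spacing / 2.0
    origin = -half
    grid = Image3D(np.zeros(tuple(size)), origin, spacing)
    pts = grid.grid_world_coords().reshape(-1, 3)
    lower, upper = grid.world_bounds()

    scene = _Scene(half, rng)
    roi = ROIBox(
        [0.26 * half[0], 0.12 * half[1], -0.75 * half[2]],
        [0.80 * half[0], 0.80 * half[1], 0.75 * half[2]],
    )
    if np.any(roi.lower < lower) or np.any(roi.upper > upper):
        raise GeometryError("thigh ROI falls outside the phantom domain")

    g = _global_motion(rng, global_motion)
    locals_: list[FFDLattice] = []
    bg = _random_local_lattice(rng, lower, upper, 40.0, local_amplitude, pts)
    if bg is not None:
        locals_.append(bg)
    roi_lat = _random_local_lattice(rng, lower, upper, 24.0, roi_amplitude, pts, roi=roi)
    if roi_lat is not None:
        locals_.append(roi_lat)
    truth = CompositeTransform(g, locals_)

    mapped = truth.apply(pts)
    target = grid.copy(voxels=scene.intensity(mapped).reshape(grid.shape))
    labels_target = grid.copy(voxels=scene.labels(mapped).reshape(grid.shape))
    clean_source = grid.copy(voxels=scene.intensity(pts).reshape(grid.shape))
    labels_source = grid.copy(voxels=scene.labels(pts).reshape(grid.shape))

    source_vox = clean_source.voxels.copy()
    if n_impulses > 0:
        tube = np.nonzero(scene.applicator_tube(pts))[0]
        if tube.size:
            chosen = rng.choice(tube, size=min(n_impulses, tube.size), replace=False)
            impulse_value = 3.0 * float(clean_source.voxels.max())
            flat = source_vox.reshape(-1)
            flat[chosen] = impulse_value
    source = grid.copy(voxels=source_vox)

    frac = np.array([0.25, 0.5, 0.75])
    axes = [roi.lower[a] + frac * (roi.upper[a] - roi.lower[a]) for a in range(3)]
    lm_pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    names = [f"lm{i:02d}" for i in range(lm_pts.shape[0])]
    landmarks_target = LandmarkSet(names, lm_pts)
    landmarks_source = LandmarkSet(list(names), truth.apply(lm_pts))

    truth_obj = PhantomTruth(
        target=target, source=source, clean_source=clean_source,
        truth_transform=truth, labels_target=labels_target,
        labels_source=labels_source, landmarks_target=landmarks_target,
        landmarks_source=landmarks_source,
        dose_source=None,  # type: ignore[arg-type]
        roi=roi, seed=int(seed),
        tumor_center=scene.tumor_c.copy(), half_extent=half.copy(),
    )
    truth_obj.dose_source = make_dose(truth_obj, "gaussian_blob")
    return truth_obj


def make_dose(truth: PhantomTruth, pattern: str = "gaussian_blob") -> DoseGrid:
    """Synthetic fraction dose aligned to the source geometry (Gy).

    ``uniform``: 2 Gy everywhere.  ``gaussian_blob``: 6 Gy peak centred on the
    tumour, sigma = a quarter of the smallest half-extent.
    """
    src = truth.clean_source
    if pattern == "uniform":
        values = np.full(src.shape, 2.0)
    elif pattern == "gaussian_blob":
        pts = src.grid_world_coords().reshape(-1, 3)
        sigma = 0.25 * float(min(truth.half_extent))
        r2 = np.sum((pts - truth.tumor_center) ** 2, axis=1)
        values = (6.0 * np.exp(-r2 / (2.0 * sigma**2))).reshape(src.shape)
    else:
        raise ConfigError(f"unknown dose pattern {pattern!r}")
    return DoseGrid(values, src.origin.copy(), src.spacing.copy(),
                    src.direction.copy(), fraction_label=f"phantom-{pattern}")
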