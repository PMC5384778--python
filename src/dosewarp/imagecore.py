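"""Volume data model, world/voxel geometry, and format I/O.

The internal world frame is the DICOM patient frame (LPS, millimetres).
NIfTI stores an RAS affine, so axes are flipped on read and flipped back on
write.  A volume is a rank-3 scalar array indexed ``voxels[i, j, k]`` whose
voxel *centres* sit at ``world = origin + direction @ (spacing * index)``
(0-based continuous indices).

Supported formats:

* NIfTI-1 ``.nii`` / ``.nii.gz``            (nibabel)
* MetaImage ``.mha`` / ``.mhd``             (SimpleITK)
* DICOM CT series (a directory of slices)   (pydicom, read only)
* Landmarks: CSV ``name,x,y,z`` in world mm (LPS)
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, GeometryError, ParseError, ValidationError

__all__ = [
    "Image3D",
    "ROIBox",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "world_to_voxel",
    "voxel_to_world",
    "contains_point",
]

#: sign flips taking RAS (NIfTI) coordinates into LPS (DICOM) and back.
_RAS2LPS = np.diag([-1.0, -1.0, 1.0])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Image3D:
    """A scalar volume with world-space geometry.

    Parameters
    ----------
    voxels:
        Rank-3 array of intensities (Hounsfield-like arbitrary units).
    origin:
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    spacing:
        Strictly positive voxel size per axis (mm).
    direction:
        3x3 orthonormal matrix whose columns are the world directions of the
        voxel axes.
    frame_tag:
        Label of the world convention; everything internal is ``"LPS"``.
    """

    voxels: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame_tag: str = "LPS"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValidationError("voxel array must be rank 3 and non-empty")
        if not np.all(self.spacing > 0):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValidationError("direction matrix must be orthonormal to 1e-6")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def copy(self, voxels: np.ndarray | None = None) -> "Image3D":
        return Image3D(
            self.voxels.copy() if voxels is None else voxels,
            self.origin.copy(), self.spacing.copy(), self.direction.copy(),
            self.frame_tag,
        )

    def is_axis_aligned(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.direction, np.eye(3), atol=atol))

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of the voxel-centre hull."""
        n = np.array(self.shape, dtype=float)
        corners = []
        for cx in (0.0, n[0] - 1):
            for cy in (0.0, n[1] - 1):
                for cz in (0.0, n[2] - 1):
                    corners.append(voxel_to_world(self, (cx, cy, cz)))
        corners = np.array(corners)
        return corners.min(axis=0), corners.max(axis=0)

    def grid_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n, dtype=float) for n in self.shape), indexing="ij"),
            axis=-1,
        )
        return idx * self.spacing @ self.direction.T + self.origin

    def same_grid(self, other: "Image3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


@dataclass
class ROIBox:
    """Axis-aligned region-of-interest box in world mm."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float).reshape(3)
        self.upper = np.asarray(self.upper, dtype=float).reshape(3)
        if not np.all(self.lower < self.upper):
            raise ValidationError(
                f"ROI lower bound must be < upper componentwise: {self.lower} vs {self.upper}"
            )

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.all((pts >= self.lower) & (pts <= self.upper), axis=1)

    def dilated(self, margin) -> "ROIBox":
        margin = np.broadcast_to(np.asarray(margin, dtype=float), (3,))
        return ROIBox(self.lower - margin, self.upper + margin)


@dataclass
class LandmarkSet:
    """Named 3D points in world mm (order is meaningful: correspondence is by index)."""

    names: list[str]
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.names = list(self.names)
        if len(self.names) != self.points.shape[0]:
            raise ValidationError("landmark names and points disagree in length")
        if self.points.shape[0] < 1:
            raise ValidationError("a landmark set needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("landmark coordinates must be finite")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("landmark names must be unique")

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# world <-> voxel
# ---------------------------------------------------------------------------

def world_to_voxel(img: Image3D, p) -> np.ndarray:
    """Continuous (not rounded) voxel index of world point(s) ``p`` (mm)."""
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    q = (np.atleast_2d(p) - img.origin) @ img.direction / img.spacing
    return q[0] if single else q


def voxel_to_world(img: Image3D, idx) -> np.ndarray:
    """World position (mm) of continuous voxel index/indices ``idx``."""
    idx = np.asarray(idx, dtype=float)
    single = idx.ndim == 1
    p = (np.atleast_2d(idx) * img.spacing) @ img.direction.T + img.origin
    return p[0] if single else p


def contains_point(img: Image3D, p) -> np.ndarray:
    """True where the world point lies inside the voxel-centre hull."""
    q = np.atleast_2d(world_to_voxel(img, p))
    n = np.array(img.shape, dtype=float)
    ok = np.all((q >= 0.0) & (q <= n - 1.0), axis=1)
    return ok if np.asarray(p).ndim > 1 else bool(ok[0])


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def _read_nifti(path: str) -> Image3D:
    import nibabel as nib

    try:
        nii = nib.load(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    data = np.asarray(nii.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path!r}: expected a 3D volume, got shape {data.shape}")
    affine = nii.affine
    m_lps = _RAS2LPS @ affine[:3, :3]
    origin = _RAS2LPS @ affine[:3, 3]
    spacing = np.linalg.norm(m_lps, axis=0)
    direction = m_lps / spacing
    return Image3D(data, origin, spacing, direction)


def _write_nifti(img: Image3D, path: str) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = _RAS2LPS @ (img.direction * img.spacing)
    affine[:3, 3] = _RAS2LPS @ img.origin
    nib.save(nib.Nifti1Image(img.voxels, affine), path)


def _read_meta(path: str) -> Image3D:
    import SimpleITK as sitk

    try:
        im = sitk.ReadImage(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read MetaImage volume {path!r}: {exc}") from exc
    arr = sitk.GetArrayFromImage(im)  # (z, y, x)
    if arr.ndim != 3:
        raise FormatError(f"{path!r}: expected a 3D volume, got shape {arr.shape}")
    direction = np.array(im.GetDirection(), dtype=float).reshape(3, 3)
    return Image3D(arr.transpose(2, 1, 0), np.array(im.GetOrigin()),
                   np.array(im.GetSpacing()), direction)


def _write_meta(img: Image3D, path: str) -> None:
    import SimpleITK as sitk

    im = sitk.GetImageFromArray(np.ascontiguousarray(img.voxels.transpose(2, 1, 0)))
    im.SetOrigin(tuple(img.origin))
    im.SetSpacing(tuple(img.spacing))
    im.SetDirection(tuple(img.direction.ravel()))
    sitk.WriteImage(im, path)


def _read_dicom_series(path: str) -> Image3D:
    import pydicom

    files = sorted(
        os.path.join(path, f) for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:  # noqa: BLE001
            continue
        if hasattr(ds, "ImagePositionPatient") and hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM image slices in directory {path!r}")

    first = slices[0]
    orient = np.array(first.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = orient[:3], orient[3:]
    normal = np.cross(row_dir, col_dir)
    slices.sort(key=lambda ds: float(np.dot(normal, np.array(ds.ImagePositionPatient, float))))

    positions = np.array([np.dot(normal, np.array(s.ImagePositionPatient, float)) for s in slices])
    if len(slices) < 2:
        raise GeometryError(f"DICOM series in {path!r} has a single slice; need >= 2")
    steps = np.diff(positions)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-3):
        raise GeometryError(
            f"DICOM series in {path!r} has inconsistent slice spacing: {steps}"
        )
    dz = float(steps[0])
    ps = np.array(first.PixelSpacing, dtype=float)  # (row, col) spacing

    def _slice_values(ds):
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept

    # pixel_array is (rows, cols); axis 0 of the volume is the column (x) axis
    vol = np.stack([_slice_values(s).T for s in slices], axis=-1)
    origin = np.array(slices[0].ImagePositionPatient, dtype=float)
    direction = np.column_stack([row_dir, col_dir, normal])
    spacing = np.array([ps[1], ps[0], dz])
    return Image3D(vol, origin, spacing, direction)


def read_volume(path: str) -> Image3D:
    """Read a volume (NIfTI, MetaImage, or DICOM series directory) into LPS."""
    if os.path.isdir(path):
        return _read_dicom_series(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if lower.endswith((".mha", ".mhd")):
        return _read_meta(path)
    raise FormatError(f"unsupported volume format: {path!r}")


def write_volume(img: Image3D, path: str) -> None:
    """Write a volume; the format is chosen from the file extension."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FormatError(f"parent directory does not exist: {parent!r}")
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        _write_nifti(img, path)
    elif lower.endswith((".mha", ".mhd")):
        _write_meta(img, path)
    else:
        raise FormatError(f"unsupported volume format: {path!r}")


# ---------------------------------------------------------------------------
# landmark I/O
# ---------------------------------------------------------------------------

def read_landmarks(path: str) -> LandmarkSet:
    """Read a ``name,x,y,z`` CSV of world-mm landmarks (order preserved)."""
    names: list[str] = []
    pts: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header] != ["name", "x", "y", "z"]:
            raise ParseError(f"{path!r}: expected header 'name,x,y,z', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise ParseError(f"{path!r} line {lineno}: expected 4 fields, got {len(row)}")
            name = row[0].strip()
            if name in names:
                raise ParseError(f"{path!r} line {lineno}: duplicate landmark name {name!r}")
            try:
                coords = [float(c) for c in row[1:]]
            except ValueError as exc:
                raise ParseError(f"{path!r} line {lineno}: non-numeric coordinate") from exc
            names.append(name)
            pts.append(coords)
    if not names:
        raise ParseError(f"{path!r}: no landmarks found")
    return LandmarkSet(names, np.array(pts))


def write_landmarks(ls: LandmarkSet, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y", "z"])
        for name, p in zip(ls.names, ls.points):
            writer.writerow([name, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])
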