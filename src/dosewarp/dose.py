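"""Dose-grid I/O, dose warping, and accumulation across treatment fractions.

A fraction's dose grid lives on its own geometry (Gy).  To accumulate doses
delivered in different fractions, each fraction's grid is pulled back through
the registration transform onto the reference grid (linear interpolation,
0 Gy outside the footprint) and the grids are summed voxelwise:

    D_total(x) = D_ref(x) + sum_i D_i(T_i(x))

Accumulation is pointwise physical-dose summation; radiobiological weighting
(EQD2) and energy-preserving resampling are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, GeometryError, ValidationError
from .imagecore import Image3D, read_volume, write_volume
from .transforms import CompositeTransform, warp_image

__all__ = ["DoseGrid", "read_dose", "write_dose", "warp_dose",
           "accumulate_dose", "dose_report"]


@dataclass
class DoseGrid:
    """Dose values (Gy) on an Image3D-like geometry."""

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    fraction_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("dose values must be >= 0 Gy")

    @classmethod
    def from_image(cls, img: Image3D, fraction_label: str = "") -> "DoseGrid":
        return cls(img.voxels, img.origin, img.spacing, img.direction, fraction_label)

    @property
    def image(self) -> Image3D:
        return Image3D(self.values, self.origin, self.spacing, self.direction)

    def same_grid(self, other: "DoseGrid", atol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


def _read_rtdose(path: str) -> DoseGrid:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read DICOM file {path!r}: {exc}") from exc
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError(f"{path!r} is not an RTDOSE object")
    for attr in ("DoseGridScaling", "GridFrameOffsetVector", "ImagePositionPatient",
                 "ImageOrientationPatient", "PixelSpacing"):
        if not hasattr(ds, attr):
            raise FormatError(f"{path!r}: RTDOSE missing required field {attr}")
    scaling = float(ds.DoseGridScaling)
    raw = ds.pixel_array.astype(np.float64)  # (frames, rows, cols)
    if raw.ndim != 3:
        raise FormatError(f"{path!r}: expected a multi-frame RTDOSE grid")
    values = raw.transpose(2, 1, 0) * scaling  # (cols=x, rows=y, frames=z)
    if np.any(values < 0):
        raise ValidationError(f"{path!r}: negative stored dose")

    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if offsets.size != raw.shape[0]:
        raise FormatError(f"{path!r}: GridFrameOffsetVector does not match frame count")
    steps = np.diff(offsets)
    if offsets.size > 1 and (np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-3)):
        raise GeometryError(f"{path!r}: non-uniform RTDOSE frame offsets")
    dz = float(steps[0]) if offsets.size > 1 else 1.0

    orient = np.asarray(ds.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = orient[:3], orient[3:]
    direction = np.column_stack([row_dir, col_dir, np.cross(row_dir, col_dir)])
    ps = np.asarray(ds.PixelSpacing, dtype=float)  # (row, col)
    origin = np.asarray(ds.ImagePositionPatient, dtype=float) \
        + offsets[0] * direction[:, 2]
    return DoseGrid(values, origin, np.array([ps[1], ps[0], dz]), direction,
                    fraction_label=str(getattr(ds, "SeriesDescription", "")))


def read_dose(path: str) -> DoseGrid:
    """Read a dose grid: DICOM RTDOSE (scaled to Gy) or a NIfTI dose volume."""
    lower = path.lower()
    if lower.endswith(".dcm") or lower.endswith(".dicom"):
        return _read_rtdose(path)
    if lower.endswith((".nii", ".nii.gz", ".mha", ".mhd")):
        img = read_volume(path)
        return DoseGrid.from_image(img)
    # fall back to sniffing DICOM
    try:
        return _read_rtdose(path)
    except FormatError:
        raise FormatError(f"unsupported dose format: {path!r}") from None


def write_dose(d: DoseGrid, path: str) -> None:
    write_volume(d.image, path)


def warp_dose(d: DoseGrid, T: CompositeTransform, ref: Image3D,
              fraction_label: str | None = None) -> DoseGrid:
    """Pull a fraction dose onto the reference grid through ``T`` (linear
    interpolation, exactly 0 Gy outside the dose footprint)."""
    warped = warp_image(d.image, T, ref, interp="linear", pad_value=0.0)
    return DoseGrid(warped.voxels, ref.origin.copy(), ref.spacing.copy(),
                    ref.direction.copy(),
                    d.fraction_label if fraction_label is None else fraction_label)


def accumulate_dose(reference: DoseGrid, warped: list[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of the reference dose and already-warped fraction doses.

    All grids must share the reference geometry exactly; there is no silent
    resampling.  Summation order is the input order.
    """
    total = reference.values.copy()
    for i, w in enumerate(warped):
        if not reference.same_grid(w):
            raise GeometryError(
                f"fraction {i} is not on the reference dose grid; warp it first"
            )
        total = total + w.values
    return DoseGrid(total, reference.origin.copy(), reference.spacing.copy(),
                    reference.direction.copy(), fraction_label="total")


def dose_report(total: DoseGrid, labels: Image3D) -> dict[int, dict[str, float]]:
    """Per-label dose statistics {label: {mean_gy, max_gy, voxels}}."""
    if total.values.shape != labels.voxels.shape:
        raise GeometryError("labels must be on the dose grid")
    lab = np.asarray(labels.voxels).astype(np.int64)
    out: dict[int, dict[str, float]] = {}
    for value in sorted(np.unique(lab)):
        if value == 0:
            continue
        sel = lab == value
        vals = total.values[sel]
        out[int(value)] = {
            "mean_gy": float(vals.mean()),
            "max_gy": float(vals.max()),
            "voxels": int(sel.sum()),
        }
    return out
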