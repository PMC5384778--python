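"""Denoising, reorientation, and resampling onto a common grid.

The source (HDR-BT) volume is first reoriented to the target (EBRT) axes,
then resampled to the target voxel grid, and both volumes are median-filtered
to attenuate the bright-voxel noise the brachytherapy applicator induces.
The median filter is nonlinear and edge-preserving, which is why it is used
instead of a Gaussian: a single bright impulse vanishes entirely while bone
edges stay sharp.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._interp import INTERPOLATORS, sample_at_index
from .errors import ConfigError
from .imagecore import Image3D, voxel_to_world, world_to_voxel

__all__ = ["median_denoise", "resample_to_reference", "reorient_to"]


def median_denoise(img: Image3D, radius=1) -> Image3D:
    """Median filter with a ``(2r+1)^3`` box; borders use edge replication.

    ``radius`` may be a scalar or per-axis triple; radius 0 on an axis leaves
    that axis untouched.
    """
    radius = np.broadcast_to(np.asarray(radius, dtype=int), (3,))
    if np.any(radius < 0):
        raise ConfigError(f"median radius must be >= 0 per axis, got {radius}")
    size = tuple(2 * int(r) + 1 for r in radius)
    if size == (1, 1, 1):
        return img.copy()
    filtered = ndimage.median_filter(img.voxels, size=size, mode="nearest")
    return img.copy(voxels=filtered)


def resample_to_reference(src: Image3D, ref: Image3D, interp: str = "linear",
                          pad_value: float | None = None) -> Image3D:
    """Resample ``src`` onto ``ref``'s grid; outside the source footprint the
    output is exactly ``pad_value`` (default: the source minimum)."""
    if interp not in INTERPOLATORS:
        raise ConfigError(f"unknown interpolator {interp!r}; choose one of {INTERPOLATORS}")
    if pad_value is None:
        pad_value = float(src.voxels.min())
    if src.same_grid(ref):
        out = src.copy()
        out.voxels = np.asarray(out.voxels, dtype=np.float64)
        return out
    pts_world = ref.grid_world_coords().reshape(-1, 3)
    idx = world_to_voxel(src, pts_world)
    vals = sample_at_index(src.voxels, idx, interp, pad_value)
    return Image3D(vals.reshape(ref.shape), ref.origin.copy(), ref.spacing.copy(),
                   ref.direction.copy(), ref.frame_tag)


def reorient_to(src: Image3D, ref: Image3D, interp: str = "linear") -> Image3D:
    """Regrid ``src`` onto axes parallel to ``ref``'s, keeping tissue world
    positions unchanged.

    The output grid uses ``ref``'s direction matrix and covers the world
    bounding box of ``src`` at (axis-matched) source spacing.  If the source is
    already aligned with the reference the volume is returned voxel-identical.
    """
    if np.allclose(src.direction, ref.direction, atol=1e-9):
        return src.copy()
    # match each reference axis to the closest source axis to carry its spacing
    dots = np.abs(ref.direction.T @ src.direction)  # [ref_axis, src_axis]
    spacing = np.empty(3)
    for a in range(3):
        spacing[a] = src.spacing[int(np.argmax(dots[a]))]
    # bounding box of the source voxel-centre hull in reference-axis coordinates
    n = np.array(src.shape, dtype=float)
    corners = []
    for cx in (0.0, n[0] - 1):
        for cy in (0.0, n[1] - 1):
            for cz in (0.0, n[2] - 1):
                corners.append(voxel_to_world(src, (cx, cy, cz)))
    q = np.array(corners) @ ref.direction  # coordinates along reference axes
    qlo, qhi = q.min(axis=0), q.max(axis=0)
    shape = tuple(int(np.floor((qhi[a] - qlo[a]) / spacing[a])) + 1 for a in range(3))
    origin = ref.direction @ qlo
    grid = Image3D(np.zeros(shape), origin, spacing, ref.direction.copy(), ref.frame_tag)
    return resample_to_reference(src, grid, interp=interp)
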