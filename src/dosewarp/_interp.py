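"""Scalar-volume interpolation at continuous voxel indices.

All samplers share the same footprint rule: a point whose continuous index
falls outside the voxel-centre hull ``[0, n-1]`` on any axis returns the pad
value *exactly*.  Inside the volume, kernels wider than one voxel (Catmull-Rom,
Lanczos) use edge replication for the out-of-range taps.

Supported schemes (names used across the package and the CLI):

``nearest``        round to the closest voxel
``linear``         trilinear
``c1_spline``      Catmull-Rom cubic (interpolating, C1)
``cubic_bspline``  cubic B-spline interpolation (prefiltered)
``windowed_sinc``  Lanczos-3 windowed sinc, weights renormalised to sum 1
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ConfigError

INTERPOLATORS = ("nearest", "linear", "c1_spline", "cubic_bspline", "windowed_sinc")

_BLOCK = 1 << 15  # points per block for the wide separable kernels


def _footprint_mask(pts: np.ndarray, shape) -> np.ndarray:
    n = np.asarray(shape, dtype=float)
    return np.all((pts >= 0.0) & (pts <= n - 1.0), axis=1)


def _nearest(vol, pts):
    idx = np.rint(pts).astype(np.intp)
    for a in range(3):
        np.clip(idx[:, a], 0, vol.shape[a] - 1, out=idx[:, a])
    return vol[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.float64)


def _trilinear(vol, pts):
    n = vol.shape
    c = np.floor(pts).astype(np.intp)
    for a in range(3):
        np.clip(c[:, a], 0, n[a] - 2, out=c[:, a])
    f = pts - c
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    x0, y0, z0 = c[:, 0], c[:, 1], c[:, 2]
    v000 = vol[x0, y0, z0]
    v001 = vol[x0, y0, z0 + 1]
    v010 = vol[x0, y0 + 1, z0]
    v011 = vol[x0, y0 + 1, z0 + 1]
    v100 = vol[x0 + 1, y0, z0]
    v101 = vol[x0 + 1, y0, z0 + 1]
    v110 = vol[x0 + 1, y0 + 1, z0]
    v111 = vol[x0 + 1, y0 + 1, z0 + 1]
    lo = (v000 * (1.0 - fz) + v001 * fz) * (1.0 - fy) + (v010 * (1.0 - fz) + v011 * fz) * fy
    hi = (v100 * (1.0 - fz) + v101 * fz) * (1.0 - fy) + (v110 * (1.0 - fz) + v111 * fz) * fy
    return lo * (1.0 - fx) + hi * fx


def _catmull_rom_weights(t: np.ndarray) -> np.ndarray:
    """Catmull-Rom weights for taps at offsets (-1, 0, 1, 2), shape (N, 4)."""
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            0.5 * (-t3 + 2.0 * t2 - t),
            0.5 * (3.0 * t3 - 5.0 * t2 + 2.0),
            0.5 * (-3.0 * t3 + 4.0 * t2 + t),
            0.5 * (t3 - t2),
        ],
        axis=1,
    )


def _lanczos3_weights(t: np.ndarray) -> np.ndarray:
    """Lanczos-3 weights for taps at offsets (-2..3), renormalised, shape (N, 6)."""
    offsets = np.arange(-2, 4, dtype=float)
    x = t[:, None] - offsets[None, :]
    w = np.sinc(x) * np.sinc(x / 3.0)
    w[np.abs(x) >= 3.0] = 0.0
    return w / w.sum(axis=1, keepdims=True)


def _separable(vol, pts, weight_fn, first_offset, ntap):
    n = vol.shape
    out = np.empty(pts.shape[0])
    for start in range(0, pts.shape[0], _BLOCK):
        blk = pts[start:start + _BLOCK]
        c = np.floor(blk).astype(np.intp)
        t = blk - c
        wx = weight_fn(t[:, 0])
        wy = weight_fn(t[:, 1])
        wz = weight_fn(t[:, 2])
        taps = np.arange(first_offset, first_offset + ntap, dtype=np.intp)
        ix = np.clip(c[:, 0, None] + taps, 0, n[0] - 1)
        iy = np.clip(c[:, 1, None] + taps, 0, n[1] - 1)
        iz = np.clip(c[:, 2, None] + taps, 0, n[2] - 1)
        vals = vol[ix[:, :, None, None], iy[:, None, :, None], iz[:, None, None, :]]
        out[start:start + _BLOCK] = np.einsum("nijk,ni,nj,nk->n", vals, wx, wy, wz)
    return out


def sample_at_index(vol: np.ndarray, pts: np.ndarray, interp: str, pad: float) -> np.ndarray:
    """Sample ``vol`` at continuous indices ``pts`` (N, 3); pad outside."""
    if interp not in INTERPOLATORS:
        raise ConfigError(
            f"unknown interpolator {interp!r}; choose one of {INTERPOLATORS}"
        )
    vol = np.asarray(vol, dtype=np.float64)
    pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
    inside = _footprint_mask(pts, vol.shape)
    out = np.full(pts.shape[0], float(pad))
    if not inside.any():
        return out
    p_in = pts[inside]
    if interp == "nearest":
        vals = _nearest(vol, p_in)
    elif interp == "linear":
        vals = _trilinear(vol, p_in)
    elif interp == "c1_spline":
        vals = _separable(vol, p_in, _catmull_rom_weights, -1, 4)
    elif interp == "windowed_sinc":
        vals = _separable(vol, p_in, _lanczos3_weights, -2, 6)
    else:  # cubic_bspline
        vals = ndimage.map_coordinates(vol, p_in.T, order=3, mode="nearest")
    out[inside] = vals
    return out
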