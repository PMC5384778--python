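"""Voxel-wise similarity metrics over an image pair on a common grid.

The information-theoretic metrics are built on a joint intensity histogram
with equal-width bins spanning each image's [min, max] over the evaluation
mask, hard bin assignment, and entropies in nats:

* normalised mutual information  NMI = (H(A) + H(B)) / H(A, B), in [1, 2]
* mutual information             MI  = H(A) + H(B) - H(A, B)
* joint entropy                  H(A, B)

plus mean squared difference (SSD), Pearson correlation (CC), and the
correlation ratio eta^2 of B given binned A.  NMI is the default registration
metric because it is robust to the differing intensity statistics of EBRT and
HDR-BT acquisitions; CC is the evaluation surrogate reported after
registration.

For use inside the optimizer, metric polarity is normalised to
"larger is better" by :func:`metric_score` (SSD and joint entropy negated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, GeometryError, UndefinedMetricError
from .imagecore import Image3D

__all__ = [
    "JointHistogram",
    "joint_histogram",
    "nmi",
    "mutual_information",
    "joint_entropy",
    "ssd",
    "correlation",
    "correlation_ratio",
    "metric_score",
    "METRICS",
]

METRICS = ("nmi", "mi", "ssd", "cc", "je", "cr")


@dataclass
class JointHistogram:
    counts: np.ndarray
    bin_edges_a: np.ndarray
    bin_edges_b: np.ndarray
    n_samples: int


def _as_values(img) -> np.ndarray:
    return img.voxels if isinstance(img, Image3D) else np.asarray(img)


def _paired_values(a, b, mask):
    va, vb = _as_values(a), _as_values(b)
    if isinstance(a, Image3D) and isinstance(b, Image3D) and not a.same_grid(b):
        raise GeometryError("similarity inputs must share one grid")
    if va.shape != vb.shape:
        raise GeometryError(f"shape mismatch: {va.shape} vs {vb.shape}")
    va = va.astype(np.float64).ravel()
    vb = vb.astype(np.float64).ravel()
    keep = np.isfinite(va) & np.isfinite(vb)
    if mask is not None:
        keep &= _as_values(mask).astype(bool).ravel()
    va, vb = va[keep], vb[keep]
    if va.size == 0:
        raise UndefinedMetricError("no valid voxels in the evaluation mask")
    return va, vb


def bin_values(values: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    """Hard equal-width binning: floor((v - lo) * bins / (hi - lo)), clipped.

    A degenerate range (hi == lo) puts everything in bin 0; values outside
    [lo, hi] are clamped into the edge bins.
    """
    values = np.asarray(values, dtype=np.float64)
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int32)
    inv_w = bins / (hi - lo)
    idx = np.floor((values - lo) * inv_w).astype(np.int64)
    return np.clip(idx, 0, bins - 1).astype(np.int32)


def joint_histogram(a, b, bins: int = 64, mask=None) -> JointHistogram:
    """Joint intensity histogram with equal-width per-image bins."""
    if bins < 2:
        raise UndefinedMetricError(f"need at least 2 bins, got {bins}")
    va, vb = _paired_values(a, b, mask)
    lo_a, hi_a = float(va.min()), float(va.max())
    lo_b, hi_b = float(vb.min()), float(vb.max())
    ia = bin_values(va, lo_a, hi_a, bins)
    ib = bin_values(vb, lo_b, hi_b, bins)
    counts = np.bincount(ia.astype(np.int64) * bins + ib, minlength=bins * bins)
    counts = counts.reshape(bins, bins)
    return JointHistogram(
        counts,
        np.linspace(lo_a, hi_a, bins + 1),
        np.linspace(lo_b, hi_b, bins + 1),
        int(va.size),
    )


def entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy (nats) of integer counts: log N - sum(n log n)/N."""
    counts = np.asarray(counts, dtype=np.float64).ravel()
    n = counts.sum()
    if n <= 0:
        return 0.0
    nz = counts[counts > 0]
    return float(np.log(n) - np.sum(nz * np.log(nz)) / n)


def _entropies(hist: JointHistogram) -> tuple[float, float, float]:
    h_a = entropy_from_counts(hist.counts.sum(axis=1))
    h_b = entropy_from_counts(hist.counts.sum(axis=0))
    h_ab = entropy_from_counts(hist.counts)
    return h_a, h_b, h_ab


def nmi(a, b, bins: int = 64, mask=None) -> float:
    """Normalised mutual information (H(A)+H(B))/H(A,B); 2 for identical
    images, 1 for independent ones."""
    h_a, h_b, h_ab = _entropies(joint_histogram(a, b, bins, mask))
    if h_ab == 0.0:
        raise UndefinedMetricError("NMI undefined: both images are constant")
    return (h_a + h_b) / h_ab


def mutual_information(a, b, bins: int = 64, mask=None) -> float:
    h_a, h_b, h_ab = _entropies(joint_histogram(a, b, bins, mask))
    return h_a + h_b - h_ab


def joint_entropy(a, b, bins: int = 64, mask=None) -> float:
    return _entropies(joint_histogram(a, b, bins, mask))[2]


def ssd(a, b, mask=None) -> float:
    """Mean squared intensity difference (0 iff equal on the mask)."""
    va, vb = _paired_values(a, b, mask)
    return float(np.mean((va - vb) ** 2))


def correlation(a, b, mask=None) -> float:
    """Pearson correlation coefficient of the paired intensities."""
    va, vb = _paired_values(a, b, mask)
    sa, sb = va.std(), vb.std()
    if sa == 0.0 or sb == 0.0:
        raise UndefinedMetricError("correlation undefined for a constant image")
    return float(np.mean((va - va.mean()) * (vb - vb.mean())) / (sa * sb))


def correlation_ratio(a, b, bins: int = 64, mask=None) -> float:
    """eta^2 of B explained by binned A, in [0, 1]."""
    va, vb = _paired_values(a, b, mask)
    var_b = vb.var()
    if var_b == 0.0:
        raise UndefinedMetricError("correlation ratio undefined for constant B")
    ia = bin_values(va, float(va.min()), float(va.max()), bins).astype(np.int64)
    counts = np.bincount(ia, minlength=bins).astype(np.float64)
    sums = np.bincount(ia, weights=vb, minlength=bins)
    nz = counts > 0
    means = np.zeros(bins)
    means[nz] = sums[nz] / counts[nz]
    between = np.sum(counts[nz] * (means[nz] - vb.mean()) ** 2) / vb.size
    return float(between / var_b)


def metric_score(name: str, a, b, bins: int = 64, mask=None) -> float:
    """Evaluate a metric by config name with polarity 'larger is better'."""
    if name == "nmi":
        return nmi(a, b, bins, mask)
    if name == "mi":
        return mutual_information(a, b, bins, mask)
    if name == "ssd":
        return -ssd(a, b, mask)
    if name == "cc":
        return correlation(a, b, mask)
    if name == "je":
        return -joint_entropy(a, b, bins, mask)
    if name == "cr":
        return correlation_ratio(a, b, bins, mask)
    raise ConfigError(f"unknown metric {name!r}; choose one of {METRICS}")
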