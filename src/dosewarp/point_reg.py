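"""Point-set registration: closed-form rigid/affine fits and the
landmark-driven FFD (LFFD).

``fit_rigid_points`` / ``fit_affine_points`` solve the least-squares alignment
of corresponding landmark pairs (target points P onto source points Q) for
coarse initialisation.  ``fit_lffd`` fits the free control points of a
ROI-masked B-spline lattice so that ``p_i + u(p_i)`` lands on ``q_i`` in the
mean-square sense.  Because the displacement is linear in the control-point
coefficients, the fit is an exactly quadratic problem and is solved in closed
form by ridge-regularised normal equations rather than by iterative descent;
control points outside the (dilated) ROI stay frozen bit-exactly.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateConfigurationError, GeometryError, ValidationError
from .imagecore import LandmarkSet
from .transforms import AffineTransform, FFDLattice, RigidTransform, ffd_displacement

__all__ = ["fit_rigid_points", "fit_affine_points", "fit_lffd", "landmark_rms"]


def _paired_points(P: LandmarkSet, Q: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    if len(P) != len(Q):
        raise ValidationError(f"landmark sets differ in size: {len(P)} vs {len(Q)}")
    return P.points.copy(), Q.points.copy()


def landmark_rms(P: LandmarkSet, Q: LandmarkSet, transform=None) -> float:
    """RMS distance between (transformed) P and Q — the target registration error."""
    p, q = _paired_points(P, Q)
    if transform is not None:
        p = transform.apply(p)
    return float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1))))


def fit_rigid_points(P: LandmarkSet, Q: LandmarkSet) -> RigidTransform:
    """Least-squares rigid alignment of P onto Q (orthogonal Procrustes,
    reflections excluded).

    Needs at least three non-collinear points.
    """
    p, q = _paired_points(P, Q)
    if len(P) < 3:
        raise DegenerateConfigurationError(
            f"rigid point fit needs >= 3 landmark pairs, got {len(P)}"
        )
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    if np.linalg.matrix_rank(p0, tol=1e-9 * max(1.0, np.abs(p0).max())) < 2:
        raise DegenerateConfigurationError("rigid point fit: landmarks are collinear")
    u, _, vt = np.linalg.svd(q0.T @ p0)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return RigidTransform(rot, qc - rot @ pc)


def fit_affine_points(P: LandmarkSet, Q: LandmarkSet) -> AffineTransform:
    """Least-squares affine fit ``q ~ M p + t``; exact when N = 4 points are in
    general position."""
    p, q = _paired_points(P, Q)
    if len(P) < 4:
        raise DegenerateConfigurationError(
            f"affine point fit needs >= 4 landmark pairs, got {len(P)}"
        )
    design = np.hstack([p, np.ones((len(P), 1))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(design).max())) < 4:
        raise DegenerateConfigurationError("affine point fit: landmarks are affinely dependent")
    sol, *_ = np.linalg.lstsq(design, q, rcond=None)
    return AffineTransform(sol[:3].T, sol[3])


def fit_lffd(P: LandmarkSet, Q: LandmarkSet, lat: FFDLattice,
             ridge: float = 1e-6) -> FFDLattice:
    """Fit the free control points of ``lat`` so ``p_i + u(p_i)`` matches ``q_i``.

    Minimises ``mean_i |p_i + u(p_i) - q_i|^2 + ridge * |phi_free|^2`` in
    closed form.  Frozen control points (``free_mask`` false) keep their
    coefficients bit-exactly; their displacement contribution is moved to the
    right-hand side.  All landmarks must lie in the lattice support.
    """
    p, q = _paired_points(P, Q)
    if ridge < 0:
        raise ValidationError("ridge weight must be >= 0")
    if not lat.covers(p).all():
        bad = np.nonzero(~lat.covers(p))[0]
        raise GeometryError(
            f"landmarks outside lattice support (indices {bad.tolist()})"
        )
    free_idx = np.nonzero(lat.free_mask.ravel())[0]
    if free_idx.size == 0:
        raise DegenerateConfigurationError("LFFD fit: the lattice has no free control points")

    n_pts = len(P)
    n_nodes = int(np.prod(lat.shape))
    col_of_node = -np.ones(n_nodes, dtype=int)
    col_of_node[free_idx] = np.arange(free_idx.size)

    base, w = lat.basis_weights(p)
    design = np.zeros((n_pts, free_idx.size))
    ny, nz = lat.shape[1], lat.shape[2]
    for l in range(4):
        for m in range(4):
            for r in range(4):
                node = ((base[:, 0] + l) * ny + (base[:, 1] + m)) * nz + (base[:, 2] + r)
                cols = col_of_node[node]
                weights = w[:, 0, l] * w[:, 1, m] * w[:, 2, r]
                sel = cols >= 0
                design[np.nonzero(sel)[0], cols[sel]] += weights[sel]

    frozen = lat.copy()
    frozen.coefficients = frozen.coefficients.copy()
    frozen.coefficients.reshape(-1, 3)[free_idx] = 0.0
    rhs_pts = q - p - ffd_displacement(frozen, p)

    gram = design.T @ design / n_pts + ridge * np.eye(free_idx.size)
    sol = np.linalg.solve(gram, design.T @ rhs_pts / n_pts)

    out = lat.copy()
    out.coefficients.reshape(-1, 3)[free_idx] = sol
    return out
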