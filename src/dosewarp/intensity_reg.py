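"""Intensity-driven registration: rigid, affine, multi-resolution FFD, and the
multi-phase landmark+intensity (LFFD+FFD) strategy.

Protocol
--------
All registrations run over a Gaussian image pyramid (smooth with sigma = 1
voxel, decimate by 2 per coarser level; 3 levels by default) and maximise a
similarity metric (NMI by default) with deterministic regular-step gradient
ascent.  For the FFD, the control-point lattice covers the whole target
domain plus a one-spacing margin; its spacing starts at ``control_spacing0``
(20 mm by default) on the coarsest level and is halved per finer level by
B-spline subdivision, which carries the displacement field across levels
exactly.  Histogram ranges are frozen per level from the images at the start
of that level so the objective is stationary during optimisation.

The multi-phase strategy first fits a landmark-driven FFD (LFFD) whose free
control points are restricted to a region of interest around the locally
large ("thigh") deformation — a cascade of ROI-masked lattices at 40, 20,
10 mm fitted in closed form to the landmark residuals — and then runs
intensity FFD on top with the LFFD lattices kept frozen, so the landmark
correction is never undone.  The total transform stays additive throughout:
``T(x) = T_global(x) + sum_k u_k(x)``.

The engine requires axis-aligned (preprocessed) volumes; oblique direct
registration is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from . import _kernels
from .errors import ConfigError, GeometryError, RegistrationError
from .imagecore import Image3D, LandmarkSet, ROIBox
from .optimize import OptimizerConfig, gradient_ascent
from .point_reg import fit_lffd
from .similarity import (bin_values, correlation, entropy_from_counts,
                         metric_score, nmi)
from .transforms import (AffineTransform, CompositeTransform, FFDLattice,
                         RigidTransform, bspline_basis_vector, identity_transform,
                         jacobian_determinant, make_lattice_covering,
                         subdivide_lattice, warp_image)

logger = logging.getLogger("dosewarp")

__all__ = ["RegistrationConfig", "register_linear", "register_ffd",
           "register_multiphase", "evaluate_registration", "FFDObjective",
           "gaussian_pyramid"]


@dataclass
class RegistrationConfig:
    """Configuration of one registration stage (the parameter-file analog).

    ``step`` / ``min_step`` default per context when left as ``None``:
    1 unit (1 mm translation / 0.01 rad rotation / 1 % scale) for linear
    models, 0.4 x control spacing for the FFD.
    """

    metric: str = "nmi"
    bins: int = 32
    optimizer: str = "gradient"
    max_iter: int = 100
    step: float | None = None
    min_step: float | None = None
    tol: float = 1e-5
    fd_step: float = 0.5
    pyramid_levels: int = 3
    control_spacing0: float = 20.0
    spacing_halving: bool = True
    level_iter_scale: float = 2.0  # iteration budget multiplier per coarser level
    interp: str = "linear"
    mask: Image3D | None = None
    init_transform: CompositeTransform | None = None

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ConfigError(f"pyramid_levels must be >= 1, got {self.pyramid_levels}")
        if self.control_spacing0 <= 0:
            raise ConfigError(f"control_spacing0 must be > 0, got {self.control_spacing0}")

    def optimizer_config(self, default_step: float, max_iter: int | None = None,
                         ) -> OptimizerConfig:
        step = default_step if self.step is None else self.step
        return OptimizerConfig(
            optimizer="steepest" if self.optimizer == "steepest" else "gradient",
            max_iter=self.max_iter if max_iter is None else max_iter, step=step,
            min_step=self.min_step, tol=self.tol, fd_step=self.fd_step,
        )

    def level_max_iter(self, level: int, levels: int) -> int:
        """Iteration budget per level; coarser levels get more (they are cheap)."""
        return max(1, int(round(self.max_iter * self.level_iter_scale ** (levels - 1 - level))))

    def effective_bins(self, n_samples: int) -> int:
        """Cap the bin count so the joint histogram stays populated
        (roughly n_samples >= 8 * bins^2)."""
        return int(min(self.bins, max(8, np.sqrt(n_samples / 8.0))))


# ---------------------------------------------------------------------------
# pyramid
# ---------------------------------------------------------------------------

def gaussian_pyramid(img: Image3D, levels: int) -> list[Image3D]:
    """Coarse-to-fine pyramid: sigma = 1 voxel smoothing then x2 decimation."""
    out = [img]
    cur = img
    for _ in range(levels - 1):
        smoothed = ndimage.gaussian_filter(np.asarray(cur.voxels, dtype=float), sigma=1.0)
        dec = smoothed[::2, ::2, ::2]
        cur = Image3D(dec, cur.origin.copy(), cur.spacing * 2.0,
                      cur.direction.copy(), cur.frame_tag)
        out.append(cur)
    return out[::-1]


def _decimated_mask(mask: Image3D | None, factor: int, level_img: Image3D):
    if mask is None:
        return None
    m = np.asarray(mask.voxels).astype(bool)[::factor, ::factor, ::factor]
    if m.shape != level_img.shape:
        raise GeometryError("mask does not match the target grid")
    return m


def _require_axis_aligned(*imgs: Image3D) -> None:
    for im in imgs:
        if not im.is_axis_aligned(atol=1e-6):
            raise GeometryError(
                "the registration engine requires axis-aligned volumes; "
                "run reorient/resample preprocessing first"
            )


# ---------------------------------------------------------------------------
# frozen-range metric evaluation
# ---------------------------------------------------------------------------

def _frozen_metric(name, t_vals, s_vals, bins, lo_t, hi_t, lo_s, hi_s):
    """Metric with histogram edges frozen to precomputed per-level ranges."""
    if name in ("nmi", "mi", "je"):
        tb = bin_values(t_vals, lo_t, hi_t, bins).astype(np.int64)
        sb = bin_values(s_vals, lo_s, hi_s, bins).astype(np.int64)
        counts = np.bincount(tb * bins + sb, minlength=bins * bins).reshape(bins, bins)
        h_a = entropy_from_counts(counts.sum(axis=1))
        h_b = entropy_from_counts(counts.sum(axis=0))
        h_ab = entropy_from_counts(counts)
        if name == "je":
            return -h_ab
        if name == "mi":
            return h_a + h_b - h_ab
        return (h_a + h_b) / h_ab if h_ab > 0.0 else 2.0
    return metric_score(name, t_vals, s_vals, bins=bins)


# ---------------------------------------------------------------------------
# linear registration
# ---------------------------------------------------------------------------

_ROT_UNIT = 0.01   # rad per parameter unit
_MAT_UNIT = 0.01   # matrix-entry change per parameter unit


def _linear_transform_from_params(model: str, params: np.ndarray, center: np.ndarray):
    if model == "rigid":
        rot = Rotation.from_euler("xyz", params[:3] * _ROT_UNIT).as_matrix()
        t = params[3:6] + center - rot @ center
        return RigidTransform(rot, t)
    m = np.eye(3) + params[:9].reshape(3, 3) * _MAT_UNIT
    t = params[9:12] + center - m @ center
    return AffineTransform(m, t)


def _linear_params_from_transform(model: str, g, center: np.ndarray) -> np.ndarray:
    if g is None:
        return np.zeros(6 if model == "rigid" else 12)
    mat, trans = (g.rotation, g.translation) if isinstance(g, RigidTransform) \
        else (g.matrix, g.translation)
    t = trans - center + mat @ center
    if model == "rigid":
        if not isinstance(g, RigidTransform):
            u, _, vt = np.linalg.svd(mat)
            mat = u @ vt
            if np.linalg.det(mat) < 0:
                mat = u @ np.diag([1, 1, -1]) @ vt
        angles = Rotation.from_matrix(mat).as_euler("xyz") / _ROT_UNIT
        return np.concatenate([angles, t])
    return np.concatenate([(mat - np.eye(3)).ravel() / _MAT_UNIT, t])


def register_linear(target: Image3D, source: Image3D, model: str = "rigid",
                    cfg: RegistrationConfig | None = None,
                    history_out: list | None = None) -> CompositeTransform:
    """Optimise a rigid (6-parameter) or affine (12-parameter) transform
    maximising the configured metric over a Gaussian pyramid."""
    if model not in ("rigid", "affine"):
        raise ConfigError(f"linear model must be 'rigid' or 'affine', got {model!r}")
    cfg = cfg or RegistrationConfig()
    _require_axis_aligned(target, source)

    lower, upper = target.world_bounds()
    center = (lower + upper) / 2.0
    init_global = cfg.init_transform.global_transform if cfg.init_transform else None
    params = _linear_params_from_transform(model, init_global, center)

    pyr_t = gaussian_pyramid(target, cfg.pyramid_levels)
    pyr_s = gaussian_pyramid(source, cfg.pyramid_levels)
    pad = float(source.voxels.min())

    for lev, (t_img, s_img) in enumerate(zip(pyr_t, pyr_s)):
        factor = 2 ** (cfg.pyramid_levels - 1 - lev)
        m = _decimated_mask(cfg.mask, factor, t_img)
        pts = t_img.grid_world_coords().reshape(-1, 3)
        t_vals = np.asarray(t_img.voxels, dtype=float).ravel()
        if m is not None:
            sel = m.ravel()
            if not sel.any():
                raise RegistrationError("registration mask is empty at a pyramid level")
            pts, t_vals = pts[sel], t_vals[sel]
        s_idx_scale = 1.0 / s_img.spacing
        s_origin = s_img.origin
        s_vol = np.asarray(s_img.voxels, dtype=float)

        def sample(p):
            T = _linear_transform_from_params(model, p, center)
            pos = (T.apply(pts) - s_origin) * s_idx_scale
            out = np.empty(pos.shape[0])
            # edge-clamped sampling keeps the objective continuous at the
            # footprint boundary (strict padding puts a cliff exactly on the
            # aligned-grid manifold)
            _kernels.trilinear_grid(s_vol, pos.reshape(1, 1, -1, 3), pad,
                                    out.reshape(1, 1, -1), True)
            return out

        lo_t, hi_t = float(t_vals.min()), float(t_vals.max())
        s0 = sample(params)
        lo_s, hi_s = float(s0.min()), float(s0.max())
        bins = cfg.effective_bins(t_vals.size)

        def objective(p):
            return _frozen_metric(cfg.metric, t_vals, sample(p), bins,
                                  lo_t, hi_t, lo_s, hi_s)

        opt_cfg = cfg.optimizer_config(
            default_step=1.0, max_iter=cfg.level_max_iter(lev, cfg.pyramid_levels))
        params, state = gradient_ascent(objective, params, opt_cfg)
        logger.info("linear %s level %d/%d: %s %.6f -> %.6f (%d accepted steps)",
                    model, lev + 1, cfg.pyramid_levels, cfg.metric,
                    state.history[0][1], state.objective, len(state.history) - 1)
        if history_out is not None:
            history_out.append((lev, state.history))

    g = _linear_transform_from_params(model, params, center)
    init_locals = list(cfg.init_transform.locals_) if cfg.init_transform else []
    return CompositeTransform(g, init_locals)


# ---------------------------------------------------------------------------
# FFD objective (NMI with histogram-local finite-difference gradient)
# ---------------------------------------------------------------------------

class FFDObjective:
    """NMI of (target, source warped through base transform + lattice).

    The gradient with respect to the lattice coefficients recomputes only the
    histogram contribution of the voxels inside each control point's support,
    which equals full recomputation up to floating-point roundoff.
    """

    def __init__(self, target: Image3D, source: Image3D, lat: FFDLattice,
                 base: CompositeTransform, bins: int = 32,
                 mask: np.ndarray | None = None):
        self.lat = lat
        self.bins = int(bins)
        self.shape = target.shape
        self.src = np.ascontiguousarray(source.voxels, dtype=np.float64)
        self.pad = float(self.src.min())
        self.inv_sp = np.ascontiguousarray(1.0 / source.spacing)

        pts = target.grid_world_coords().reshape(-1, 3)
        base_world = base.apply(pts)
        self.base_pos = np.ascontiguousarray(
            ((base_world - source.origin) / source.spacing).reshape(self.shape + (3,))
        )

        # separable lattice weights along each (axis-aligned) target axis
        self._W, self._cb = [], []
        for a in range(3):
            coords = target.origin[a] + np.arange(self.shape[a]) * target.spacing[a]
            g = (coords - lat.grid_origin[a]) / lat.spacing[a]
            cell = np.floor(g).astype(np.int64)
            self._W.append(np.ascontiguousarray(bspline_basis_vector(g - cell)))
            self._cb.append(np.ascontiguousarray(cell - 1))
        # support voxel ranges per control-point index along each axis
        self._vlo, self._vhi = [], []
        for a in range(3):
            n_cp = lat.shape[a]
            cb = self._cb[a]
            lo = np.searchsorted(cb, np.arange(n_cp) - 3, side="left")
            hi = np.searchsorted(cb, np.arange(n_cp), side="right")
            self._vlo.append(np.ascontiguousarray(lo.astype(np.int64)))
            self._vhi.append(np.ascontiguousarray(hi.astype(np.int64)))

        t_vals = np.asarray(target.voxels, dtype=float)
        sel = np.ones(self.shape, dtype=bool) if mask is None else mask
        if not sel.any():
            raise RegistrationError("registration mask is empty")
        self._lo_t = float(t_vals[sel].min())
        self._hi_t = float(t_vals[sel].max())
        t_bin = bin_values(t_vals, self._lo_t, self._hi_t, self.bins)
        t_bin[~sel] = -1
        self.t_bin = np.ascontiguousarray(t_bin, dtype=np.int32)
        self.n_samples = int(sel.sum())
        t_counts = np.bincount(t_bin[sel].astype(np.int64), minlength=self.bins)
        self.h_a = entropy_from_counts(t_counts)

        # source histogram range frozen from the initial coefficients
        s0 = self._sample(lat.coefficients)
        self.lo_b = float(s0.min())
        hi_b = float(s0.max())
        self.inv_w_b = self.bins / (hi_b - self.lo_b) if hi_b > self.lo_b else 0.0

        self._free = np.ascontiguousarray(lat.free_mask, dtype=np.uint8)
        nvox = int(np.prod(self.shape))
        self._buf_ob = np.empty(nvox, dtype=np.int32)
        self._buf_nb = np.empty(nvox, dtype=np.int32)
        self._buf_tb = np.empty(nvox, dtype=np.int32)

    # -- core evaluation ---------------------------------------------------
    def _sample(self, C: np.ndarray) -> np.ndarray:
        u = np.empty(self.shape + (3,))
        _kernels.ffd_grid_disp(np.ascontiguousarray(C), self._W[0], self._cb[0],
                               self._W[1], self._cb[1], self._W[2], self._cb[2], u)
        pos = self.base_pos + u * self.inv_sp
        s = np.empty(self.shape)
        # strict pad (not clamp): out-of-footprint samples take the source
        # minimum, which penalises boundary drift of the deformation
        _kernels.trilinear_grid(self.src, pos, self.pad, s, False)
        self._last_pos = pos
        return s

    def _bin_source(self, s: np.ndarray) -> np.ndarray:
        if self.inv_w_b == 0.0:
            return np.zeros(self.shape, dtype=np.int32)
        idx = np.floor((s - self.lo_b) * self.inv_w_b)
        return np.clip(idx, 0, self.bins - 1).astype(np.int32)

    def _counts(self, s_bin: np.ndarray):
        joint = np.zeros((self.bins, self.bins), dtype=np.int64)
        marg_b = np.zeros(self.bins, dtype=np.int64)
        _kernels.joint_counts_grid(self.t_bin, s_bin, self.bins, joint, marg_b)
        return joint, marg_b

    def __call__(self, flat: np.ndarray) -> float:
        C = np.asarray(flat, dtype=float).reshape(self.lat.shape + (3,))
        s = self._sample(C)
        joint, marg_b = self._counts(self._bin_source(s))
        h_b = entropy_from_counts(marg_b)
        h_ab = entropy_from_counts(joint)
        return (self.h_a + h_b) / h_ab if h_ab > 0.0 else 2.0

    def gradient(self, flat: np.ndarray, h: float) -> np.ndarray:
        C = np.asarray(flat, dtype=float).reshape(self.lat.shape + (3,))
        s = self._sample(C)
        s_bin = np.ascontiguousarray(self._bin_source(s))
        joint, marg_b = self._counts(s_bin)
        grad = np.zeros(self.lat.shape + (3,))
        _kernels.nmi_fd_gradient(
            self.src, self._last_pos, s_bin, self.t_bin, joint, marg_b,
            self.n_samples, self.h_a, self.lo_b, self.inv_w_b, self.bins,
            self.pad, h, self.inv_sp,
            self._W[0], self._cb[0], self._W[1], self._cb[1], self._W[2], self._cb[2],
            self._vlo[0], self._vhi[0], self._vlo[1], self._vhi[1],
            self._vlo[2], self._vhi[2],
            self._free, grad, self._buf_ob, self._buf_nb, self._buf_tb, False,
        )
        return grad.ravel()


# ---------------------------------------------------------------------------
# FFD registration
# ---------------------------------------------------------------------------

def register_ffd(target: Image3D, source: Image3D,
                 cfg: RegistrationConfig | None = None,
                 lattice: FFDLattice | None = None,
                 history_out: list | None = None) -> CompositeTransform:
    """Multi-resolution FFD registration (all control points free by default).

    Per level the images are decimated by 2 and the lattice spacing is halved
    by subdivision (coarsest level uses ``control_spacing0``).  The optimised
    lattice is appended to the init transform's locals; the init transform
    itself is never modified.
    """
    cfg = cfg or RegistrationConfig()
    _require_axis_aligned(target, source)
    if cfg.metric != "nmi":
        raise ConfigError("FFD registration currently optimises the NMI metric")
    init = cfg.init_transform or identity_transform()
    base = CompositeTransform(init.global_transform, list(init.locals_))

    if lattice is None:
        lower, upper = target.world_bounds()
        lattice = make_lattice_covering(lower, upper, cfg.control_spacing0)
    lat = lattice.copy()

    pyr_t = gaussian_pyramid(target, cfg.pyramid_levels)
    pyr_s = gaussian_pyramid(source, cfg.pyramid_levels)

    for lev, (t_img, s_img) in enumerate(zip(pyr_t, pyr_s)):
        if lev > 0 and cfg.spacing_halving:
            lat = subdivide_lattice(lat)
        if any(n < 4 for n in lat.shape):
            raise ConfigError(f"lattice too small at level {lev}: {lat.shape}")
        factor = 2 ** (cfg.pyramid_levels - 1 - lev)
        m = _decimated_mask(cfg.mask, factor, t_img)
        n_vox = int(np.prod(t_img.shape)) if m is None else int(m.sum())
        obj = FFDObjective(t_img, s_img, lat, base, bins=cfg.effective_bins(n_vox), mask=m)
        opt_cfg = cfg.optimizer_config(
            default_step=0.4 * float(lat.spacing.min()),
            max_iter=cfg.level_max_iter(lev, cfg.pyramid_levels))
        free3 = np.repeat(lat.free_mask.ravel(), 3)
        params, state = gradient_ascent(obj, lat.coefficients.ravel(), opt_cfg,
                                        gradient_fn=obj.gradient, free_mask=free3)
        lat.coefficients = params.reshape(lat.shape + (3,))
        logger.info("ffd level %d/%d (spacing %s mm): nmi %.6f -> %.6f "
                    "(%d accepted steps)", lev + 1, cfg.pyramid_levels,
                    lat.spacing.round(2).tolist(), state.history[0][1],
                    state.objective, len(state.history) - 1)
        if history_out is not None:
            history_out.append((lev, state.history))

    return CompositeTransform(base.global_transform, list(base.locals_) + [lat])


def register_multiphase(target: Image3D, source: Image3D, thigh_roi: ROIBox,
                        P: LandmarkSet, Q: LandmarkSet,
                        cfg_lffd: RegistrationConfig | None = None,
                        cfg_ffd: RegistrationConfig | None = None,
                        ridge: float = 1e-6, strict_roi: bool = True,
                        history_out: list | None = None) -> CompositeTransform:
    """LFFD (landmark phase, ROI-constrained) followed by intensity FFD.

    Phase 1 fits a cascade of ROI-masked lattices (spacing halved per level,
    40 mm initial by default) to the landmark residuals in closed form.
    Phase 2 runs :func:`register_ffd` with the phase-1 lattices frozen in the
    init transform, per the additive two-part local model.

    With ``strict_roi`` (default) the phase-1 lattices use the literal
    piecewise ROI form — displacement exactly zero outside the ROI — so the
    landmark correction cannot bleed into well-aligned tissue through the
    B-spline support (2 control spacings, a large fraction of a small
    volume at the 40 mm level).  ``strict_roi=False`` keeps the smooth
    everywhere-evaluated variant, leaving phase 2 to undo any spill-over.
    """
    cfg_lffd = cfg_lffd or RegistrationConfig(control_spacing0=40.0)
    cfg_ffd = cfg_ffd or RegistrationConfig()
    init = cfg_ffd.init_transform or cfg_lffd.init_transform or identity_transform()

    lower, upper = target.world_bounds()
    current = CompositeTransform(init.global_transform, list(init.locals_))
    lffd_lats: list[FFDLattice] = []
    spacing = float(cfg_lffd.control_spacing0)
    for lev in range(cfg_lffd.pyramid_levels):
        lat = make_lattice_covering(lower, upper, spacing, roi=thigh_roi,
                                    strict_piecewise=strict_roi)
        if lat.n_free == 0:
            raise RegistrationError("no lattice control points are free inside the ROI")
        # remaining residual after the transform accumulated so far
        q_adj = P.points + (Q.points - current.apply(P.points))
        fitted = fit_lffd(P, LandmarkSet(list(Q.names), q_adj), lat, ridge=ridge)
        lffd_lats.append(fitted)
        current.locals_.append(fitted)
        res = float(np.sqrt(np.mean(np.sum((current.apply(P.points) - Q.points) ** 2, axis=1))))
        logger.info("lffd level %d/%d (spacing %.1f mm): landmark RMS %.3f mm",
                    lev + 1, cfg_lffd.pyramid_levels, spacing, res)
        if not cfg_lffd.spacing_halving:
            break
        spacing /= 2.0

    cfg2 = replace(cfg_ffd, init_transform=CompositeTransform(
        init.global_transform, list(init.locals_) + lffd_lats))
    return register_ffd(target, source, cfg2, history_out=history_out)


# ---------------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------------

def evaluate_registration(target: Image3D, warped_source: Image3D,
                          labels_target: Image3D | None = None,
                          warped_labels: Image3D | None = None,
                          transform: CompositeTransform | None = None,
                          bins: int = 64, mask=None) -> dict:
    """Deterministic metric report: CC, NMI, per-label Dice, min Jacobian."""
    if not target.same_grid(warped_source):
        raise GeometryError("evaluation inputs must share one grid")
    report: dict = {
        "cc": correlation(target, warped_source, mask=mask),
        "nmi": nmi(target, warped_source, bins=bins, mask=mask),
        "dice": {},
        "jacobian_min": None,
    }
    if labels_target is not None and warped_labels is not None:
        lt = np.asarray(labels_target.voxels).astype(np.int64)
        lw = np.asarray(warped_labels.voxels).astype(np.int64)
        labels = sorted(set(np.unique(lt)) | set(np.unique(lw)))
        for lab in labels:
            if lab == 0:
                continue
            a, b = lt == lab, lw == lab
            denom = a.sum() + b.sum()
            if denom == 0:
                continue
            report["dice"][int(lab)] = float(2.0 * np.logical_and(a, b).sum() / denom)
    if transform is not None:
        report["jacobian_min"] = float(jacobian_determinant(transform, target).min())
    return report


def warp_with(target: Image3D, source: Image3D, T: CompositeTransform,
              interp: str = "linear") -> Image3D:
    """Convenience: pull the source onto the target grid through ``T``."""
    return warp_image(source, T, target, interp=interp)
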