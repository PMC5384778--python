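"""Generic maximisation of a similarity objective over transform parameters.

Two ascent schemes are provided, both deterministic (no randomness anywhere):

* ``gradient`` (default): regular-step gradient ascent.  The gradient is the
  central finite difference of the objective; each iteration moves by a fixed
  step length along the normalised gradient, the step halves whenever the
  candidate fails to improve, and the run stops when the step drops below
  ``min_step``, the improvement falls below ``tol``, or ``max_iter`` is hit.
  Accepted steps strictly increase the objective, so the reported history is
  monotone.
* ``steepest``: same gradient direction but with a golden-section line search
  along it each iteration.

Frozen parameters (``free_mask`` false) are never perturbed and their
gradient entries are exactly zero without ever being evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, NumericalError, RegistrationError

__all__ = ["OptimizerConfig", "OptimizerState", "finite_diff_gradient",
           "gradient_ascent"]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class OptimizerConfig:
    """Knobs of the ascent loop (the ``par_in`` analog).

    ``step`` is in the parameter's own units (mm for FFD coefficients and
    translations); ``fd_step`` is the finite-difference perturbation.
    """

    optimizer: str = "gradient"  # or "steepest"
    max_iter: int = 100
    step: float = 1.0
    step_shrink: float = 0.5
    min_step: float | None = None  # default: step / 64
    tol: float = 1e-5
    fd_step: float = 0.5

    def __post_init__(self) -> None:
        if self.optimizer not in ("gradient", "steepest"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if (self.max_iter <= 0 or self.step <= 0 or not 0 < self.step_shrink < 1
                or self.tol < 0 or self.fd_step <= 0):
            raise ConfigError("optimizer config values must be positive")
        if self.min_step is None:
            self.min_step = self.step / 64.0
        if self.min_step <= 0:
            raise ConfigError("min_step must be positive")


@dataclass
class OptimizerState:
    iteration: int = 0
    objective: float = -np.inf
    step_length: float = 0.0
    gradient_norm: float = 0.0
    converged: bool = False
    history: list[tuple[int, float]] = field(default_factory=list)


def finite_diff_gradient(objective, params: np.ndarray, h: float,
                         free_mask: np.ndarray | None = None) -> np.ndarray:
    """Central-difference gradient; frozen entries are exactly 0 and never
    evaluated."""
    if h <= 0:
        raise ConfigError(f"finite-difference step must be > 0, got {h}")
    params = np.asarray(params, dtype=float)
    grad = np.zeros_like(params)
    for i in range(params.size):
        if free_mask is not None and not free_mask[i]:
            continue
        p = params.copy()
        p[i] = params[i] + h
        f_plus = objective(p)
        p[i] = params[i] - h
        f_minus = objective(p)
        if not (np.isfinite(f_plus) and np.isfinite(f_minus)):
            raise NumericalError(f"objective non-finite when perturbing parameter {i}")
        grad[i] = (f_plus - f_minus) / (2.0 * h)
    return grad


def _golden_section(f, lo: float, hi: float, n_iter: int = 24) -> float:
    """Maximiser of f on [lo, hi] by golden-section search (deterministic)."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(n_iter):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return c if fc >= fd else d


def gradient_ascent(objective, params0: np.ndarray, config: OptimizerConfig | None = None,
                    gradient_fn=None, free_mask: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, OptimizerState]:
    """Maximise ``objective`` from ``params0``.

    ``gradient_fn(params, h)``, when given, replaces the generic finite
    difference (used for the histogram-local FFD gradient).  Returns the best
    parameters and the optimizer state with its monotone objective history.
    """
    cfg = config or OptimizerConfig()
    params = np.array(params0, dtype=float)
    if free_mask is not None:
        free_mask = np.asarray(free_mask, dtype=bool).ravel()
        frozen_values = params[~free_mask].copy()
    f = objective(params)
    if not np.isfinite(f):
        raise RegistrationError("objective is not finite at the initial parameters")
    state = OptimizerState(objective=f, step_length=cfg.step, history=[(0, f)])
    step = cfg.step
    for it in range(1, cfg.max_iter + 1):
        if gradient_fn is not None:
            grad = np.asarray(gradient_fn(params, cfg.fd_step), dtype=float).ravel()
            if free_mask is not None:
                grad = np.where(free_mask, grad, 0.0)
        else:
            grad = finite_diff_gradient(objective, params, cfg.fd_step, free_mask)
        gnorm = float(np.linalg.norm(grad))
        gmax = float(np.abs(grad).max())
        state.gradient_norm = gnorm
        state.iteration = it
        if gmax == 0.0:
            state.converged = True
            break
        # max-normalised direction: `step` is the largest single-parameter move
        direction = grad / gmax

        if cfg.optimizer == "steepest":
            t = _golden_section(lambda s: objective(params + s * direction), 0.0, 4.0 * step)
            cand = params + t * direction
            if free_mask is not None:
                cand[~free_mask] = frozen_values
            fc = objective(cand)
            if fc > f:
                gain, params, f = fc - f, cand, fc
                state.history.append((it, f))
                state.step_length = t
                if gain < cfg.tol:
                    state.converged = True
                    break
            else:
                state.converged = True
                break
            continue

        accepted = False
        while step >= cfg.min_step:
            cand = params + step * direction
            if free_mask is not None:
                cand[~free_mask] = frozen_values
            fc = objective(cand)
            if fc > f:
                gain, params, f = fc - f, cand, fc
                state.history.append((it, f))
                accepted = True
                # recover the step after a success so one noisy rejection
                # does not strand the rest of the level at a tiny step
                step = min(step * 2.0, cfg.step)
                break
            step *= cfg.step_shrink
        state.step_length = step
        if not accepted or step < cfg.min_step:
            state.converged = True
            break
        if gain < cfg.tol:
            state.converged = True
            break
    state.objective = f
    return params, state
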