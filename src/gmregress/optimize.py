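"""Orthant-constrained conjugate-gradient descent.

The composite geometric-mean error functions are smooth and locally strictly
convex near their minimizers, but singular wherever a coefficient vanishes:
the objective is only defined (and convex) on the open orthant containing
the warm start.  The minimizer here is a modified Polak-Ribiere conjugate
gradient: whenever the Polak-Ribiere direction fails to be a direction of
descent, the steepest-descent direction is substituted.  The line search is
Armijo backtracking, with a single quadratic interpolation of the trial step
(which makes the method exact on quadratics), and an optional *orthant lock*
that caps every step at 90% of the distance to the nearest coordinate plane
so no coefficient can change sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OptimizerConfig", "Trace", "minimize", "NonConvergenceError"]


class NonConvergenceError(RuntimeError):
    """Raised when the descent stalls or hits non-finite values."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class OptimizerConfig:
    """Descent settings.

    grad_tol is *relative*: convergence is declared when the gradient norm
    falls below grad_tol * max(1, initial gradient norm).
    """

    grad_tol: float = 1e-10
    max_iter: int = 10_000
    armijo_c: float = 1e-4
    backtrack_factor: float = 0.5
    initial_step: float = 1.0
    orthant_lock: bool = True

    def __post_init__(self):
        if not (0 < self.armijo_c < 1 and 0 < self.backtrack_factor < 1):
            raise ValueError("armijo_c and backtrack_factor must lie in (0, 1)")
        if self.grad_tol <= 0 or self.max_iter <= 0 or self.initial_step <= 0:
            raise ValueError("grad_tol, max_iter and initial_step must be positive")


@dataclass
class Trace:
    """Per-run optimizer record."""

    iterations: int = 0
    final_grad_norm: float = float("nan")
    objective_history: list = field(default_factory=list)
    fallback_count: int = 0
    converged: bool = False

    def summary(self) -> dict:
        return {
            "iterations": self.iterations,
            "final_grad_norm": self.final_grad_norm,
            "initial_objective": self.objective_history[0]
            if self.objective_history
            else None,
            "final_objective": self.objective_history[-1]
            if self.objective_history
            else None,
            "fallback_count": self.fallback_count,
            "converged": self.converged,
        }


def _orthant_cap(x: np.ndarray, d: np.ndarray) -> float:
    """90% of the largest step that keeps every coordinate's sign fixed.

    Coordinate i moves toward its coordinate plane when x_i * d_i < 0 and
    would cross it at t = |x_i / d_i|.
    """
    toward = x * d < 0.0
    if not np.any(toward):
        return np.inf
    return 0.9 * float(np.min(np.abs(x[toward] / d[toward])))


def minimize(objective, gradient, x0, config: OptimizerConfig | None = None):
    """Minimize ``objective`` from ``x0``; returns ``(x, Trace)``.

    ``gradient`` may be ``None``, in which case central finite differences
    are used.  Non-finite objective values during the line search are
    treated as out-of-domain and trigger further backtracking; a non-finite
    value at an accepted point raises :class:`NonConvergenceError`.
    """
    cfg = config or OptimizerConfig()
    x = np.asarray(x0, dtype=float).copy()

    if gradient is None:
        def gradient(z, _f=objective):
            h = 1e-6 * np.maximum(np.abs(z), 1.0)
            g = np.empty_like(z)
            for i in range(z.size):
                e = np.zeros_like(z)
                e[i] = h[i]
                g[i] = (_f(z + e) - _f(z - e)) / (2 * h[i])
            return g

    trace = Trace()
    f = float(objective(x))
    if not np.isfinite(f):
        raise NonConvergenceError("objective not finite at the starting point", trace)
    trace.objective_history.append(f)
    g = np.asarray(gradient(x), dtype=float)
    if not np.all(np.isfinite(g)):
        raise NonConvergenceError("gradient not finite at the starting point", trace)
    g0_norm = float(np.linalg.norm(g))
    tol = cfg.grad_tol * max(1.0, g0_norm)
    d = -g
    step = cfg.initial_step
    stall = 0

    for it in range(cfg.max_iter):
        gnorm = float(np.linalg.norm(g))
        if gnorm <= tol:
            trace.converged = True
            break

        slope = float(g @ d)
        if slope >= 0.0:  # PR direction is not a descent direction
            d = -g
            slope = -gnorm * gnorm
            trace.fallback_count += 1

        t = step
        if cfg.orthant_lock:
            cap = _orthant_cap(x, d)
            if cap <= 0.0:
                raise NonConvergenceError(
                    "orthant lock leaves no room to move", trace
                )
            t = min(t, cap)

        # One quadratic interpolation of the trial step: fit f(0), f'(0) and
        # f(t); on a quadratic objective the fitted vertex is the exact line
        # minimum, which is what lets conjugate gradient terminate finitely.
        f_trial = float(objective(x + t * d))
        if np.isfinite(f_trial):
            denom = f_trial - f - slope * t
            if denom > 0.0:
                t_star = -slope * t * t / (2.0 * denom)
                if np.isfinite(t_star) and t_star > 0.0:
                    t_new = t_star
                    if cfg.orthant_lock:
                        t_new = min(t_new, cap)
                    t = t_new

        accepted = False
        for _ in range(200):
            x_new = x + t * d
            f_new = float(objective(x_new))
            if np.isfinite(f_new) and f_new <= f + cfg.armijo_c * t * slope:
                accepted = True
                break
            t *= cfg.backtrack_factor
        if not accepted:
            # Gradient is nonzero but no acceptable step exists at machine
            # precision: treat as converged-to-tolerance if the gradient is
            # small, otherwise report failure.
            trace.iterations = it + 1
            trace.final_grad_norm = gnorm
            if gnorm <= 1e3 * tol:
                trace.converged = True
                return x, trace
            raise NonConvergenceError(
                f"line search failed at iteration {it} (|grad|={gnorm:.3e})", trace
            )

        # Objective decreases below double-precision resolution: the iterate
        # is at the numerical floor even if the gradient tolerance (set from
        # a small warm-start gradient) is unattainable.
        if f - f_new <= 1e-15 * max(1.0, abs(f)):
            stall += 1
            if stall >= 3:
                x, f = x_new, f_new
                trace.objective_history.append(f)
                trace.iterations = it + 1
                trace.converged = True
                g = np.asarray(gradient(x), dtype=float)
                break
        else:
            stall = 0

        g_new = np.asarray(gradient(x_new), dtype=float)
        if not np.all(np.isfinite(g_new)):
            raise NonConvergenceError("gradient not finite at accepted point", trace)
        beta = float(g_new @ (g_new - g)) / float(g @ g)
        d = -g_new + max(beta, 0.0) * d
        x, f, g = x_new, f_new, g_new
        trace.objective_history.append(f)
        trace.iterations = it + 1

    trace.final_grad_norm = float(np.linalg.norm(g))
    if not trace.converged:
        trace.converged = trace.final_grad_norm <= tol
    return x, trace
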