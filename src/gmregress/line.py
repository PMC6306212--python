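"""One-dimensional subspace (line) fits in m variables.

The model is a line through the origin of the centered data:
p_2 = a_2 p_1, p_3 = a_3 p_1, ..., p_m = a_m p_1 with a_1 = 1.  Each
variable j has its own ordinary least-squares error

    E_j(a) = sum_k (p_j - (a_j / a_k) p_k) . (p_j - (a_j / a_k) p_k),

measuring the residuals with variable j as the dependent one, and the
composite error is their geometric mean E = (E_1 E_2 ... E_m)^(1/m).
Because E is a symmetric function of the E_j the fitted subspace does not
depend on which variable is labelled first (reflective invariance), and the
slope form makes it scale invariant.

Each E_j has a closed-form minimizer (a vertex of the *error simplex*):

    a_j = p_j.p_1 / p_1.p_1,      a_i = a_j p_i.p_i / (p_j.p_i)  (i != j).

For data within O(eps) of an exact line the minimizer of E agrees with the
centroid of these vertices to O(eps^2), so the centroid is both the warm
start for the descent and the reference point of the C_F fit statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataMatrix
from .evaluation import cf_general
from .optimize import OptimizerConfig, Trace, minimize

__all__ = ["LineFit", "LineRegression", "fit_line",
           "line_component_error", "line_vertex", "line_objective"]


def _gram(P: DataMatrix | np.ndarray) -> np.ndarray:
    V = P.values if isinstance(P, DataMatrix) else np.asarray(P, dtype=float)
    return V.T @ V


def _check_alpha(alpha: np.ndarray, m: int) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (m,):
        raise ValueError(f"coefficient vector must have length m={m}")
    if alpha[0] != 1.0:
        raise ValueError("the first coefficient is the reference and must be 1")
    if np.any(alpha == 0.0):
        raise ValueError("the line error is undefined where a coefficient is 0")
    return alpha


def _component_errors(G: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """All E_j at once from the Gram matrix G = P^T P."""
    ratio = alpha[:, None] / alpha[None, :]          # ratio[j, k] = a_j / a_k
    terms = np.diag(G)[:, None] - 2.0 * ratio * G + ratio**2 * np.diag(G)[None, :]
    return terms.sum(axis=1)


def line_component_error(P: DataMatrix, alpha, j: int) -> float:
    """E_j: the OLS error with variable j dependent, at coefficients alpha."""
    G = _gram(P)
    alpha = _check_alpha(alpha, G.shape[0])
    return float(_component_errors(G, alpha)[j])


def line_objective(P: DataMatrix, alpha) -> float:
    """Composite error E = (E_1 E_2 ... E_m)^(1/m)."""
    G = _gram(P)
    alpha = _check_alpha(alpha, G.shape[0])
    E = _component_errors(G, alpha)
    return float(np.prod(np.maximum(E, 0.0)) ** (1.0 / G.shape[0]))


def line_vertex(P: DataMatrix, j: int) -> np.ndarray:
    """Closed-form minimizer of E_j (full m-vector, first entry 1)."""
    G = _gram(P)
    m = G.shape[0]
    if not 0 <= j < m:
        raise ValueError(f"j must index a variable (0..{m - 1})")
    if np.any(np.abs(G[j, :]) == 0.0) or np.any(np.abs(G[0, :]) == 0.0):
        raise ValueError("orthogonal column pair: vertex formulas divide by p_j.p_i")
    alpha = np.empty(m)
    alpha[0] = 1.0
    a_j = G[j, 0] / G[0, 0]  # = 1 when j = 0
    for i in range(1, m):
        alpha[i] = a_j * G[i, i] / G[j, i] if i != j else a_j
    return alpha


def _objective_and_grad(G: np.ndarray):
    """Closures computing E and its analytic gradient in the free a_2..a_m."""
    m = G.shape[0]
    diag = np.diag(G)

    def full(alpha_free: np.ndarray) -> np.ndarray:
        return np.concatenate(([1.0], alpha_free))

    def fun(alpha_free: np.ndarray) -> float:
        alpha = full(alpha_free)
        if np.any(alpha == 0.0):
            return np.inf
        E = _component_errors(G, alpha)
        if np.any(E <= 0.0):
            return 0.0
        return float(np.exp(np.log(E).sum() / m))

    def grad(alpha_free: np.ndarray) -> np.ndarray:
        alpha = full(alpha_free)
        E = _component_errors(G, alpha)
        Eval = float(np.exp(np.log(np.maximum(E, 1e-300)).sum() / m))
        g = np.zeros(m - 1)
        for j in range(m):
            dEj = np.zeros(m - 1)
            for i in range(1, m):
                if i != j:
                    dEj[i - 1] = (2 * alpha[j] * G[j, i] / alpha[i] ** 2
                                  - 2 * alpha[j] ** 2 * diag[i] / alpha[i] ** 3)
                else:
                    ks = [k for k in range(m) if k != j]
                    dEj[i - 1] = sum(
                        -2 * G[j, k] / alpha[k] + 2 * alpha[j] * diag[k] / alpha[k] ** 2
                        for k in ks
                    )
            g += dEj / max(E[j], 1e-300)
        return (Eval / m) * g

    return fun, grad


@dataclass(frozen=True)
class LineFit:
    """Fitted line: coefficients, error simplex and diagnostics.

    ``coefficients`` is the full m-vector (a_1 = 1); ``vertices`` stacks the
    m closed-form E_j minimizers row-wise; ``centroid`` is their mean;
    ``cf`` the simplex-relative distance of the minimizer from the centroid.
    """

    coefficients: np.ndarray
    vertices: np.ndarray
    centroid: np.ndarray
    cf: float
    objective: float
    trace: Trace
    variable_names: tuple[str, ...]
    column_means: np.ndarray

    @property
    def direction(self) -> np.ndarray:
        """Unit direction vector of the fitted line."""
        return self.coefficients / np.linalg.norm(self.coefficients)

    def summary(self) -> str:
        lines = ["Geometric-mean line fit (single component)",
                 "=" * 44,
                 f"variables: {', '.join(self.variable_names)}",
                 f"model: p_j = a_j * {self.variable_names[0]}  (centered data)",
                 ""]
        lines.append(f"{'variable':<16}{'a_j':>12}{'centroid':>12}")
        for name, a, c in zip(self.variable_names, self.coefficients, self.centroid):
            lines.append(f"{name:<16}{a:>12.6g}{c:>12.6g}")
        lines += ["",
                  f"objective E     : {self.objective:.6g}",
                  f"C_F             : {self.cf:.4g}",
                  f"iterations      : {self.trace.iterations}",
                  f"final |grad|    : {self.trace.final_grad_norm:.3g}"]
        return "\n".join(lines)

    def to_record(self) -> dict:
        return {
            "kind": "line",
            "variable_names": list(self.variable_names),
            "coefficients": self.coefficients.tolist(),
            "vertices": self.vertices.tolist(),
            "centroid": self.centroid.tolist(),
            "cf": self.cf,
            "objective": self.objective,
            "column_means": self.column_means.tolist(),
            "trace": self.trace.summary(),
        }


class LineRegression:
    """Model object for the single-component (line) geometric-mean fit.

    Parameters
    ----------
    data : DataMatrix
        Centered observation table satisfying the standing assumptions
        (n >= m + 1, no zero column, no orthogonal column pair).
    """

    def __init__(self, data: DataMatrix):
        data.require_fit_ready()
        self.data = data
        self._G = _gram(data)

    @classmethod
    def from_dataframe(cls, df) -> "LineRegression":
        from .data import center

        return cls(center(DataMatrix.from_dataframe(df)))

    def vertices(self) -> np.ndarray:
        return np.vstack([line_vertex(self.data, j) for j in range(self.data.m)])

    def _polish(self, x: np.ndarray, fun, grad) -> np.ndarray:
        """Newton-polish the descent output on the stationarity system.

        The analytic gradient of the composite error is smooth where the
        objective is flat to machine precision, so a root solve from the
        converged iterate sharpens the coefficients well beyond the
        objective's floating-point floor.  Kept only if it stays in the
        same orthant and does not worsen the objective beyond roundoff.
        """
        from scipy.optimize import root

        f_ref = max(fun(x), 1e-300)
        sol = root(lambda z: grad(z) / f_ref, x, method="hybr", tol=1e-14)
        cand = sol.x
        if (np.all(np.isfinite(cand))
                and np.all(np.sign(cand) == np.sign(x))
                and fun(cand) <= fun(x) * (1 + 1e-9)):
            return cand
        return x

    def fit(self, config: OptimizerConfig | None = None) -> LineFit:
        cfg = config or OptimizerConfig()
        G = self._G
        m = G.shape[0]
        vertices = self.vertices()
        centroid = vertices.mean(axis=0)
        fun, grad = _objective_and_grad(G)

        scale = float(np.trace(G))
        f_centroid = fun(centroid[1:])
        if f_centroid <= 1e-13 * scale:
            # Exact (collinear) data: every E_j vanishes at the centroid and
            # the composite error is non-smooth there; the centroid is the
            # minimizer.
            trace = Trace(iterations=0, final_grad_norm=0.0,
                          objective_history=[f_centroid], converged=True)
            return LineFit(
                coefficients=centroid, vertices=vertices, centroid=centroid,
                cf=0.0, objective=f_centroid, trace=trace,
                variable_names=self.data.variable_names,
                column_means=self.data.column_means,
            )

        x_star, trace = minimize(fun, grad, centroid[1:], cfg)
        x_star = self._polish(x_star, fun, grad)
        alpha = np.concatenate(([1.0], x_star))
        cf = cf_general(alpha[1:], vertices[:, 1:])
        return LineFit(
            coefficients=alpha, vertices=vertices, centroid=centroid,
            cf=cf, objective=fun(x_star), trace=trace,
            variable_names=self.data.variable_names,
            column_means=self.data.column_means,
        )


def fit_line(P: DataMatrix, config: OptimizerConfig | None = None) -> LineFit:
    """Functional wrapper: fit the geometric-mean line to centered data."""
    return LineRegression(P).fit(config)
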