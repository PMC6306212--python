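"""(m-1)-dimensional subspace (hyperplane) fits.

The model is the hyperplane p_m = a_1 p_1 + ... + a_{m-1} p_{m-1} through
the origin of the centered data.  With the extended coefficient vector
alpha = (a_1, ..., a_{m-1}, -1) and P the n x m data matrix, the individual
error functions are

    E_j = ||P alpha||^2 / a_j^2     (a_m = 1 for j = m),

i.e. the common residual sum of squares weighted so that variable j plays
the dependent role, and the composite error is their geometric mean

    E = (E_1 ... E_m)^(1/m) = ||P alpha||^2 / |a_1 a_2 ... a_{m-1}|^(2/m).

Each E_j is quadratic: its minimizer (an error-simplex vertex) solves the
linear system obtained by deleting the j-th row and the m-th column of the
Gram matrix P^T P (for j = m this is exactly the OLS normal-equations
solution).  The composite minimizer satisfies the stationarity system

    (P^T P alpha)_k = ||P alpha||^2 / (m a_k),   k = 1..m-1,

which doubles as the convergence certificate of the descent; in three
variables it is equivalent to the pair of scalar equations checked by
:func:`qp_residual`.  For data within O(eps) of an exact hyperplane the
minimizer agrees with the simplex centroid to O(eps^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataMatrix
from .evaluation import cf_general
from .optimize import OptimizerConfig, Trace, minimize

__all__ = [
    "HyperplaneFit",
    "HyperplaneRegression",
    "fit_hyperplane",
    "hyperplane_component_error",
    "hyperplane_objective",
    "hyperplane_vertex",
    "qp_residual",
    "stationarity_residual",
    "predict",
]


def _gram(P: DataMatrix | np.ndarray) -> np.ndarray:
    V = P.values if isinstance(P, DataMatrix) else np.asarray(P, dtype=float)
    return V.T @ V


def _extended(alpha_free: np.ndarray) -> np.ndarray:
    return np.concatenate((alpha_free, [-1.0]))


def _check_free(alpha, m: int) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.shape != (m - 1,):
        raise ValueError(f"expected {m - 1} free coefficients, got {alpha.size}")
    return alpha


def _rss(G: np.ndarray, ext: np.ndarray) -> float:
    """||P alpha||^2 via the Gram matrix."""
    return float(ext @ G @ ext)


def hyperplane_component_error(P: DataMatrix, alpha, j: int) -> float:
    """E_j = ||P alpha||^2 / a_j^2 at the free coefficients ``alpha``.

    ``j`` indexes variables 0..m-1; the dependent variable j = m-1 has
    coefficient 1, so E_{m-1} is the plain OLS residual sum of squares.
    """
    G = _gram(P)
    m = G.shape[0]
    alpha = _check_free(alpha, m)
    if not 0 <= j < m:
        raise ValueError(f"j must index a variable (0..{m - 1})")
    ext = _extended(alpha)
    denom = 1.0 if j == m - 1 else alpha[j]
    if denom == 0.0:
        raise ValueError("E_j is undefined where the j-th coefficient is 0")
    return _rss(G, ext) / denom**2


def hyperplane_objective(P: DataMatrix, alpha) -> float:
    """Composite error E = ||P alpha||^2 / |a_1 ... a_{m-1}|^(2/m)."""
    G = _gram(P)
    m = G.shape[0]
    alpha = _check_free(alpha, m)
    if np.any(alpha == 0.0):
        raise ValueError("E is undefined where a coefficient is 0")
    ext = _extended(alpha)
    return _rss(G, ext) / np.abs(np.prod(alpha)) ** (2.0 / m)


def hyperplane_vertex(P: DataMatrix, j: int) -> np.ndarray:
    """Closed-form minimizer of E_j: the free (m-1)-vector.

    Solves the linear system whose matrix is the Gram matrix with row j and
    column m deleted and whose right-hand side is column m with entry j
    deleted.  j = m-1 yields the OLS normal-equations solution.
    """
    G = _gram(P)
    m = G.shape[0]
    if not 0 <= j < m:
        raise ValueError(f"j must index a variable (0..{m - 1})")
    rows = [i for i in range(m) if i != j]
    M = G[np.ix_(rows, range(m - 1))]
    rhs = G[rows, m - 1]
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"degenerate geometry: the E_{j} vertex system is singular"
        ) from exc
    return sol


def stationarity_residual(P: DataMatrix, alpha) -> float:
    """Maximal relative residual of the stationarity system at ``alpha``.

    Each equation (G alpha)_k = ||P alpha||^2 / (m a_k) is multiplied by
    a_k and normalized by ||P alpha||^2; the returned value is the largest
    |a_k (G alpha)_k - Q/m| / Q.  Zero residual sum of squares (exact data)
    gives 0.
    """
    G = _gram(P)
    m = G.shape[0]
    alpha = _check_free(alpha, m)
    ext = _extended(alpha)
    Q = _rss(G, ext)
    if Q == 0.0:
        return 0.0
    lhs = alpha * (G @ ext)[: m - 1]
    return float(np.abs(lhs - Q / m).max() / Q)


def qp_residual(P: DataMatrix, alpha) -> tuple[float, float]:
    """Residuals of the two normalized three-variable stationarity equations.

    For m = 3 with q = a ||x|| / ||z|| and p = b ||y|| / ||z||, the
    stationary point satisfies

        q^2 + p q cos(t_xy) + p cos(t_yz) = 1
        p^2 + p q cos(t_xy) + q cos(t_xz) = 1,

    where t_uv is the angle between the centered data vectors u and v.
    Returns the absolute deviation of each left-hand side from 1.
    """
    G = _gram(P)
    if G.shape[0] != 3:
        raise ValueError("qp_residual applies to three-variable fits only")
    a, b = _check_free(alpha, 3)
    nx, ny, nz = np.sqrt(np.diag(G))
    cos_xy = G[0, 1] / (nx * ny)
    cos_yz = G[1, 2] / (ny * nz)
    cos_xz = G[0, 2] / (nx * nz)
    q = a * nx / nz
    p = b * ny / nz
    r1 = q * q + p * q * cos_xy + p * cos_yz - 1.0
    r2 = p * p + p * q * cos_xy + q * cos_xz - 1.0
    return abs(r1), abs(r2)


def _objective_and_grad(G: np.ndarray):
    m = G.shape[0]

    def fun(alpha: np.ndarray) -> float:
        if np.any(alpha == 0.0):
            return np.inf
        ext = _extended(alpha)
        return _rss(G, ext) / np.abs(np.prod(alpha)) ** (2.0 / m)

    def grad(alpha: np.ndarray) -> np.ndarray:
        ext = _extended(alpha)
        Q = _rss(G, ext)
        c = np.abs(np.prod(alpha)) ** (2.0 / m)
        Gext = (G @ ext)[: m - 1]
        return 2.0 * Gext / c - (2.0 / m) * (Q / c) / alpha

    return fun, grad


@dataclass(frozen=True)
class HyperplaneFit:
    """Fitted hyperplane: coefficients, error simplex and diagnostics.

    ``coefficients`` are the free a_1..a_{m-1}; ``extended`` appends the -1
    of the dependent column, so ``values @ extended`` are the (centered)
    residuals.  ``vertices`` stacks the m closed-form E_j minimizers.
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
    def extended(self) -> np.ndarray:
        return _extended(self.coefficients)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the fitted hyperplane."""
        e = self.extended
        return e / np.linalg.norm(e)

    def predict(self, target, test: DataMatrix) -> np.ndarray:
        return predict(self, target, test)

    def summary(self) -> str:
        dep = self.variable_names[-1]
        lines = ["Geometric-mean hyperplane fit ((m-1) components)",
                 "=" * 50,
                 f"model: {dep} = sum_j a_j p_j  (centered data)",
                 "",
                 f"{'variable':<16}{'a_j':>12}{'centroid':>12}"]
        for name, a, c in zip(self.variable_names[:-1], self.coefficients,
                              self.centroid):
            lines.append(f"{name:<16}{a:>12.6g}{c:>12.6g}")
        lines += ["",
                  f"objective E     : {self.objective:.6g}",
                  f"C_F             : {self.cf:.4g}",
                  f"iterations      : {self.trace.iterations}",
                  f"final |grad|    : {self.trace.final_grad_norm:.3g}"]
        return "\n".join(lines)

    def to_record(self) -> dict:
        return {
            "kind": "hyperplane",
            "variable_names": list(self.variable_names),
            "coefficients": self.coefficients.tolist(),
            "extended": self.extended.tolist(),
            "vertices": self.vertices.tolist(),
            "centroid": self.centroid.tolist(),
            "cf": self.cf,
            "objective": self.objective,
            "column_means": self.column_means.tolist(),
            "trace": self.trace.summary(),
        }


class HyperplaneRegression:
    """Model object for the (m-1)-component geometric-mean fit.

    The last column of ``data`` is the nominal dependent variable (its
    extended coefficient is fixed at -1); by reflective invariance the
    fitted hyperplane — and hence every rearranged prediction — does not
    depend on that nominal choice.
    """

    def __init__(self, data: DataMatrix):
        data.require_fit_ready()
        self.data = data
        self._G = _gram(data)

    @classmethod
    def from_dataframe(cls, df, dependent: str | None = None) -> "HyperplaneRegression":
        from .data import center

        if dependent is not None:
            cols = [c for c in df.columns if c != dependent] + [dependent]
            df = df[cols]
        return cls(center(DataMatrix.from_dataframe(df)))

    def vertices(self) -> np.ndarray:
        return np.vstack(
            [hyperplane_vertex(self.data, j) for j in range(self.data.m)]
        )

    def _polish(self, x: np.ndarray, fun) -> np.ndarray:
        """Newton-polish the descent output on the stationarity system.

        The stationary point solves F_k = a_k (G alpha)_k - Q/m = 0 exactly;
        a root solve from the converged descent iterate sharpens the
        coefficients below the floating-point floor of the objective (the
        objective is flat to machine precision near the minimum, the
        stationarity equations are not).  The polished point is kept only if
        it stays in the same orthant and does not worsen the objective
        beyond roundoff.
        """
        from scipy.optimize import root

        G = self._G
        m = G.shape[0]

        def F(alpha: np.ndarray) -> np.ndarray:
            ext = _extended(alpha)
            Q = _rss(G, ext)
            scale = max(Q, 1e-300)
            return (alpha * (G @ ext)[: m - 1] - Q / m) / scale

        sol = root(F, x, method="hybr", tol=1e-14)
        cand = sol.x
        if (np.all(np.isfinite(cand))
                and np.all(np.sign(cand) == np.sign(x))
                and fun(cand) <= fun(x) * (1 + 1e-9)):
            return cand
        return x

    def fit(self, config: OptimizerConfig | None = None,
            stationarity_tol: float = 1e-6) -> HyperplaneFit:
        cfg = config or OptimizerConfig()
        G = self._G
        m = G.shape[0]
        vertices = self.vertices()
        centroid = vertices.mean(axis=0)
        fun, grad = _objective_and_grad(G)

        scale = float(np.trace(G))
        f_centroid = fun(centroid)
        if f_centroid <= 1e-13 * scale:
            trace = Trace(iterations=0, final_grad_norm=0.0,
                          objective_history=[f_centroid], converged=True)
            return HyperplaneFit(
                coefficients=centroid, vertices=vertices, centroid=centroid,
                cf=0.0, objective=f_centroid, trace=trace,
                variable_names=self.data.variable_names,
                column_means=self.data.column_means,
            )

        x_star, trace = minimize(fun, grad, centroid, cfg)
        x_star = self._polish(x_star, fun)
        res = stationarity_residual(self.data, x_star)
        if res > stationarity_tol:
            from .optimize import NonConvergenceError

            raise NonConvergenceError(
                f"stationarity residual {res:.3e} exceeds {stationarity_tol:.1e}",
                trace,
            )
        cf = cf_general(x_star, vertices)
        return HyperplaneFit(
            coefficients=x_star, vertices=vertices, centroid=centroid,
            cf=cf, objective=fun(x_star), trace=trace,
            variable_names=self.data.variable_names,
            column_means=self.data.column_means,
        )


def fit_hyperplane(P: DataMatrix, config: OptimizerConfig | None = None,
                   stationarity_tol: float = 1e-6) -> HyperplaneFit:
    """Functional wrapper: fit the geometric-mean hyperplane."""
    return HyperplaneRegression(P).fit(config, stationarity_tol)


def predict(fit: HyperplaneFit, target, test: DataMatrix) -> np.ndarray:
    """Predict one variable from the others using the fitted hyperplane.

    The single hyperplane sum_j e_j p_j = 0 (extended coefficients e) is
    rearranged for the target variable:

        p_i = -(1 / e_i) * sum_{j != i} e_j p_j.

    Because the same hyperplane is used for every target, predictions are
    independent of which variable was nominally dependent during fitting.
    ``test`` may be raw (uncentered): the *training* column means recorded
    on the fit are subtracted and added back, so predictions are returned
    in original units.
    """
    if isinstance(target, str):
        target = fit.variable_names.index(target)
    m = len(fit.variable_names)
    target = range(m)[target]
    e = fit.extended
    if e[target] == 0.0:
        raise ValueError("cannot rearrange for a variable with zero coefficient")
    if tuple(test.variable_names) != tuple(fit.variable_names):
        raise ValueError("test variables do not match the fitted variables")
    centered = test.values if test.centered else test.values - fit.column_means
    mask = np.arange(m) != target
    pred_centered = -(centered[:, mask] @ e[mask]) / e[target]
    return pred_centered + fit.column_means[target]
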