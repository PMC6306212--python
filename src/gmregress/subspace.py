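"""Intermediate-dimensional subspace fits (1 < k < m-1).

A k-dimensional model subspace in m variables is parameterized by the
default split: the last m-k variables are linear functions of the first k,

    p_dep = A p_indep,        A an (m-k) x k matrix.

Every other choice of k independent variables gives an equivalent
description, obtained by block elimination from the constraint matrix
N = [-A | I] (columns ordered as the variables): for a dependent set D with
complement I, the coefficient matrix is M = -N_D^{-1} N_I whenever the
block N_D is nonsingular.  With four variables and k = 2 there are
C(4, 2) = 6 splits; the error function attached to variable i sums the
squared residuals of every split in which i plays a dependent role (three
per variable in the 4/2 case), and the composite error is the geometric
mean (E_1 ... E_m)^(1/m) — symmetric in the variables, hence reflectively
invariant, and built from per-variable OLS errors, hence scale invariant.

Minimization runs over the entries of A with finite-difference gradients;
iterates at which a needed block is singular are treated as out of domain
(the line search backtracks), mirroring the orthant rule of the line and
hyperplane fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data import DataMatrix
from .optimize import OptimizerConfig, Trace, minimize

__all__ = [
    "SubspaceFit",
    "SubspaceRegression",
    "fit_subspace",
    "reparameterize",
    "subspace_component_error",
    "enumerate_splits",
]

#: Refuse intermediate-k fits beyond this many variables: the number of
#: splits C(m, m-k) grows combinatorially.
MAX_VARIABLES = 8


class ReparameterizationError(ValueError):
    """A requested variable split has a singular elimination block."""


def enumerate_splits(m: int, k: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All (dependent, independent) index splits with |independent| = k."""
    splits = []
    for dep in combinations(range(m), m - k):
        indep = tuple(i for i in range(m) if i not in dep)
        splits.append((dep, indep))
    return splits


def _constraint_matrix(A: np.ndarray) -> np.ndarray:
    """N = [-A | I] with columns in variable order (indep block first)."""
    d, k = A.shape
    N = np.empty((d, d + k))
    N[:, :k] = -A
    N[:, k:] = np.eye(d)
    return N


def reparameterize(A, split) -> np.ndarray:
    """Coefficient matrix of the requested (dependent, independent) split.

    ``A`` is the default-split matrix (last m-k variables as functions of
    the first k).  Returns M with p_dep = M p_indep for the requested
    split, via block elimination on the constraint matrix [-A | I].
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    dep, indep = split
    dep, indep = tuple(dep), tuple(indep)
    m = A.shape[0] + A.shape[1]
    if sorted(dep + indep) != list(range(m)):
        raise ValueError("split must partition the variable indices")
    if len(dep) != A.shape[0]:
        raise ValueError("dependent block size must match the model dimension")
    N = _constraint_matrix(A)
    N_D = N[:, dep]
    N_I = N[:, indep]
    cond = np.linalg.cond(N_D)
    if not np.isfinite(cond) or cond > 1e12:
        raise ReparameterizationError(
            f"split dep={dep} indep={indep} has a (near-)singular block"
        )
    return -np.linalg.solve(N_D, N_I)


def _component_errors(V: np.ndarray, A: np.ndarray, k: int) -> np.ndarray:
    """E_i for every variable; raises ReparameterizationError on bad splits."""
    m = V.shape[1]
    E = np.zeros(m)
    for dep, indep in enumerate_splits(m, k):
        M = reparameterize(A, (dep, indep))
        resid = V[:, dep] - V[:, indep] @ M.T
        E[list(dep)] += (resid**2).sum(axis=0)
    return E


def subspace_component_error(P: DataMatrix, A, i: int) -> float:
    """E_i: summed squared residuals over every split where i is dependent."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    k = A.shape[1]
    E = _component_errors(P.values, A, k)
    if not 0 <= i < P.m:
        raise ValueError(f"i must index a variable (0..{P.m - 1})")
    return float(E[i])


@dataclass(frozen=True)
class SubspaceFit:
    """Fitted k-dimensional subspace (default-split coefficient matrix)."""

    coeff_matrix: np.ndarray
    k: int
    component_errors: np.ndarray
    objective: float
    trace: Trace
    variable_names: tuple[str, ...]
    column_means: np.ndarray

    def basis(self) -> np.ndarray:
        """m x k orthonormal basis of the fitted subspace."""
        k = self.k
        raw = np.vstack([np.eye(k), self.coeff_matrix])
        q, _ = np.linalg.qr(raw)
        return q

    def summary(self) -> str:
        d, k = self.coeff_matrix.shape
        indep = self.variable_names[:k]
        lines = [f"Geometric-mean subspace fit (k = {k} of m = {d + k})",
                 "=" * 46,
                 f"independent block: {', '.join(indep)}",
                 ""]
        for row, name in zip(self.coeff_matrix, self.variable_names[k:]):
            terms = " + ".join(
                f"{c:.6g}*{v}" for c, v in zip(row, indep)
            )
            lines.append(f"{name} = {terms}")
        lines += ["",
                  f"objective E     : {self.objective:.6g}",
                  f"iterations      : {self.trace.iterations}"]
        return "\n".join(lines)

    def to_record(self) -> dict:
        return {
            "kind": "subspace",
            "k": self.k,
            "variable_names": list(self.variable_names),
            "coeff_matrix": self.coeff_matrix.tolist(),
            "component_errors": self.component_errors.tolist(),
            "objective": self.objective,
            "column_means": self.column_means.tolist(),
            "trace": self.trace.summary(),
        }


class SubspaceRegression:
    """Model object for the general k-dimensional geometric-mean fit.

    ``k = 1`` and ``k = m - 1`` delegate to :class:`~gmregress.line.LineRegression`
    and :class:`~gmregress.hyperplane.HyperplaneRegression`, whose fits use
    the closed-form error-simplex machinery.
    """

    def __init__(self, data: DataMatrix, k: int):
        data.require_fit_ready()
        if not 1 <= k <= data.m - 1:
            raise ValueError(f"k must lie in [1, m-1] = [1, {data.m - 1}]")
        if 1 < k < data.m - 1 and data.m > MAX_VARIABLES:
            raise ValueError(
                f"intermediate-dimensional fits are limited to m <= {MAX_VARIABLES}"
                " variables (combinatorial split count)"
            )
        self.data = data
        self.k = k

    def _warm_start(self) -> np.ndarray:
        """OLS of the default split: regress each dependent column on the
        independent block."""
        V = self.data.values
        k = self.k
        X, Y = V[:, :k], V[:, k:]
        A_t, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return A_t.T

    def fit(self, config: OptimizerConfig | None = None):
        if self.k == 1:
            from .line import LineRegression

            return LineRegression(self.data).fit(config)
        if self.k == self.data.m - 1:
            from .hyperplane import HyperplaneRegression

            return HyperplaneRegression(self.data).fit(config)

        cfg = config or OptimizerConfig(orthant_lock=False)
        if cfg.orthant_lock:
            # the subspace parameterization has no sign structure to lock
            cfg = OptimizerConfig(
                grad_tol=cfg.grad_tol, max_iter=cfg.max_iter,
                armijo_c=cfg.armijo_c, backtrack_factor=cfg.backtrack_factor,
                initial_step=cfg.initial_step, orthant_lock=False,
            )
        V = self.data.values
        m, k = self.data.m, self.k
        shape = (m - k, k)

        def fun(theta: np.ndarray) -> float:
            A = theta.reshape(shape)
            try:
                E = _component_errors(V, A, k)
            except ReparameterizationError:
                return np.inf
            if np.any(E <= 0.0):
                return 0.0
            return float(np.exp(np.log(E).sum() / m))

        A0 = self._warm_start()
        scale = float(np.trace(V.T @ V))
        f0 = fun(A0.ravel())
        if f0 <= 1e-13 * scale:
            trace = Trace(iterations=0, final_grad_norm=0.0,
                          objective_history=[f0], converged=True)
            return SubspaceFit(
                coeff_matrix=A0, k=k,
                component_errors=_component_errors(V, A0, k),
                objective=f0, trace=trace,
                variable_names=self.data.variable_names,
                column_means=self.data.column_means,
            )

        theta, trace = minimize(fun, None, A0.ravel(), cfg)
        A = theta.reshape(shape)
        for split in enumerate_splits(m, k):
            M = reparameterize(A, split)  # raises if ill-conditioned
            if np.linalg.cond(_constraint_matrix(A)[:, split[0]]) > 1e8:
                raise ReparameterizationError(
                    f"split {split[0]} is ill-conditioned at the fitted point"
                )
        return SubspaceFit(
            coeff_matrix=A, k=k,
            component_errors=_component_errors(V, A, k),
            objective=fun(theta), trace=trace,
            variable_names=self.data.variable_names,
            column_means=self.data.column_means,
        )


def fit_subspace(P: DataMatrix, k: int, config: OptimizerConfig | None = None):
    """Functional wrapper: fit a k-dimensional geometric-mean subspace."""
    return SubspaceRegression(P, k).fit(config)
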