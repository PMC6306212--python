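"""Fit statistics, prediction metrics and baseline models.

The C_F statistic generalizes the bivariate closed form: it is the largest
coordinatewise distance between the composite minimizer and the centroid of
the error simplex, relative to the simplex width in that coordinate.  Small
C_F means the centroid approximation is accurate, which in turn certifies
that the data are close to the fitted subspace.

Prediction quality on held-out data is reported with the field's standard
quantities: mean absolute deviation (MAD = ||y - y*||_1 / N), mean squared
prediction error (MSPE = ||y - y*||_2^2 / N), a normalized least-squares
error, and regression error characteristic (REC) curves — the fraction of
test residuals within each tolerance of a grid.  OLS and PCA serve as
baselines; both are delegated to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression

from .data import DataMatrix

__all__ = [
    "cf_general",
    "mad",
    "mspe",
    "normalized_lse",
    "rec_curve",
    "RECCurve",
    "integer_score_predictions",
    "pca_baseline",
    "PCABaseline",
    "ols_baseline",
]


def cf_general(coefficients, vertices) -> float:
    """Simplex-relative distance of ``coefficients`` from the vertex centroid.

    ``vertices`` has one row per error-simplex vertex.  For each coordinate
    the distance from the centroid is divided by the vertex range in that
    coordinate (coordinates with zero width contribute 0), and the maximum
    over coordinates is returned.  Reduces to |a - a_c| / |a_x - a_y| for
    two variables.
    """
    coefficients = np.asarray(coefficients, dtype=float).ravel()
    vertices = np.atleast_2d(np.asarray(vertices, dtype=float))
    if vertices.shape[0] < 2:
        raise ValueError("need at least two vertices")
    if vertices.shape[1] != coefficients.size:
        raise ValueError("coefficients and vertices disagree on dimension")
    centroid = vertices.mean(axis=0)
    widths = vertices.max(axis=0) - vertices.min(axis=0)
    dev = np.abs(coefficients - centroid)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(widths > 0.0, dev / np.where(widths > 0, widths, 1.0), 0.0)
    return float(ratios.max())


def _residuals(predicted, observed) -> np.ndarray:
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.size != observed.size:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size == 0:
        raise ValueError("need at least one observation")
    return predicted - observed


def mad(predicted, observed) -> float:
    """Mean absolute deviation ||y - y*||_1 / N on the unscaled variables."""
    r = _residuals(predicted, observed)
    return float(np.abs(r).mean())


def mspe(predicted, observed) -> float:
    """Mean squared prediction error ||y - y*||_2^2 / N (unscaled)."""
    r = _residuals(predicted, observed)
    return float((r**2).mean())


def normalized_lse(predicted, observed, training_column) -> float:
    """Squared test error normalized by N ||p_j||_1 / n.

    ``training_column`` is the (centered) training data for the same
    variable: n its length, N the test-set size.
    """
    r = _residuals(predicted, observed)
    col = np.asarray(training_column, dtype=float).ravel()
    l1 = float(np.abs(col).sum())
    if l1 == 0.0:
        raise ValueError("training column has zero norm")
    N, n = r.size, col.size
    return float((r**2).sum() / (N * l1 / n))


@dataclass(frozen=True)
class RECCurve:
    """Regression error characteristic curve.

    ``accuracy[i]`` is the fraction of test observations with absolute
    residual <= ``tolerances[i]``; non-decreasing, reaching 1 at the largest
    absolute residual.
    """

    tolerances: np.ndarray
    accuracy: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "tolerances", np.asarray(self.tolerances, float))
        object.__setattr__(self, "accuracy", np.asarray(self.accuracy, float))

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.tolerances, self.accuracy])


def rec_curve(predicted, observed, grid=None) -> RECCurve:
    """Fraction of |residual| <= t over an ascending tolerance grid.

    Default grid: 200 evenly spaced tolerances from 0 to max|residual|.
    """
    r = np.abs(_residuals(predicted, observed))
    if grid is None:
        grid = np.linspace(0.0, float(r.max()), 200)
    grid = np.asarray(grid, dtype=float).ravel()
    if np.any(np.diff(grid) < 0):
        raise ValueError("tolerance grid must be ascending")
    acc = np.array([(r <= t).mean() for t in grid])
    return RECCurve(tolerances=grid, accuracy=acc)


def integer_score_predictions(predicted, score_range=None) -> np.ndarray:
    """Convert continuous predictions back to integer scores.

    Rounds half away from zero and clamps to ``score_range`` (lo, hi) when
    given — typically the observed score range of the training data.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    rounded = np.sign(p) * np.floor(np.abs(p) + 0.5)
    if score_range is not None:
        lo, hi = score_range
        rounded = np.clip(rounded, lo, hi)
    return rounded.astype(int)


@dataclass(frozen=True)
class PCABaseline:
    """Leading singular subspace of the (optionally column-scaled) data."""

    components: np.ndarray          # (n_components, m), rows orthonormal (scaled space)
    scale: np.ndarray               # per-column divisors applied before the SVD
    column_means: np.ndarray
    variable_names: tuple[str, ...]

    def reconstruct(self, data: DataMatrix | np.ndarray) -> np.ndarray:
        """Project observations onto the subspace; original units.

        A centered ``DataMatrix`` is used as-is; raw arrays and uncentered
        tables are centered with the training means first.
        """
        if isinstance(data, DataMatrix):
            centered = data.values if data.centered else data.values - self.column_means
        else:
            centered = np.asarray(data, float) - self.column_means
        scaled = centered / self.scale
        recon = scaled @ self.components.T @ self.components
        return recon * self.scale + self.column_means


def pca_baseline(P: DataMatrix, n_components: int,
                 scaling: str = "none") -> PCABaseline:
    """PCA subspace baseline with the paper-style column scaling option.

    ``scaling="l2_sqrtn"`` divides each centered column by ||p_j||_2 /
    sqrt(n) before the SVD (unit sample standard deviation up to a common
    factor); ``"none"`` uses the raw centered columns, which makes the
    subspace rotation invariant but scale dependent.
    """
    if not P.centered:
        raise ValueError("PCA baseline requires centered data")
    if scaling not in ("none", "l2_sqrtn"):
        raise ValueError("scaling must be 'none' or 'l2_sqrtn'")
    V = P.values
    n, m = V.shape
    if scaling == "l2_sqrtn":
        scale = np.linalg.norm(V, axis=0) / np.sqrt(n)
        if np.any(scale == 0.0):
            raise ValueError("zero-norm column cannot be scaled")
    else:
        scale = np.ones(m)
    X = V / scale
    if n_components > min(n, m) or np.linalg.matrix_rank(X) < n_components:
        raise ValueError("data rank is below the requested number of components")
    model = PCA(n_components=n_components)
    model.fit(X)
    return PCABaseline(
        components=model.components_,
        scale=scale,
        column_means=P.column_means,
        variable_names=P.variable_names,
    )


def ols_baseline(P: DataMatrix, dependent: int | str = -1) -> np.ndarray:
    """Ordinary least squares of one column on the others (no intercept).

    Returns the full extended m-vector: coefficient -1 on the dependent
    column, OLS coefficients elsewhere, so that (values @ coeffs) are the
    training residuals.  Coincides with the dependent-variable vertex of the
    hyperplane error simplex.
    """
    if not P.centered:
        raise ValueError("OLS baseline requires centered data")
    if isinstance(dependent, str):
        dependent = P.variable_names.index(dependent)
    dependent = range(P.m)[dependent]
    mask = np.arange(P.m) != dependent
    X, y = P.values[:, mask], P.values[:, dependent]
    model = LinearRegression(fit_intercept=False)
    model.fit(X, y)
    extended = np.empty(P.m)
    extended[mask] = model.coef_
    extended[dependent] = -1.0
    return extended
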