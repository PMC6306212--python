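"""Closed-form two-variable regressions through the origin.

For centered data vectors ``x`` and ``y`` and the no-intercept model
``y = alpha * x`` there are several classical least-squares slopes:

* vertical OLS        alpha_y = x.y / x.x   (minimizes sum of squared
  vertical deviations)
* horizontal OLS      alpha_x = y.y / x.y
* geometric mean      alpha   = +/- sqrt(y.y / x.x), the sign of x.y —
  identical to reduced-major-axis (RMA) regression, and the minimizer of
  both the product error E_x * E_y and the triangle-area error
* perpendicular distance (the first principal axis), which is *not* scale
  invariant and therefore requires a choice of column scalings

The geometric-mean slope is scale invariant — alpha(x, y) =
(S_y / S_x) * alpha(x / S_x, y / S_y) for any positive scalings — and
reflectively invariant — alpha(y, x) = 1 / alpha(x, y).  No slope estimator
can be both scale and rotationally invariant; :func:`invariance_demo` shows
this empirically.

The fit statistic ``C_F = |alpha - alpha_c| / |alpha_x - alpha_y|`` measures
the distance of the geometric-mean slope from the centroid
``alpha_c = (alpha_x + alpha_y) / 2`` of the two OLS slopes, relative to
their separation; in closed form ``C_F = (1 - |R|) / (2 (1 + |R|))`` with
``R = cos(theta)`` the signed correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import OrthogonalColumnsError

__all__ = [
    "BivariateFit",
    "ols_slope_vertical",
    "ols_slope_horizontal",
    "gm_slope",
    "distance_slope",
    "area_slope",
    "cf_bivariate",
    "fit_bivariate",
    "invariance_demo",
    "InvarianceReport",
]

#: Column scalings offered for the distance (principal-axis) slope.
SCALINGS = ("none", "max", "l2_sqrtn", "l1_n")


def _vec(v) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two observations")
    return v


def _dots(x, y) -> tuple[float, float, float]:
    x, y = _vec(x), _vec(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    return float(x @ x), float(x @ y), float(y @ y)


def ols_slope_vertical(x, y) -> float:
    """Slope minimizing the vertical squared error sum((alpha*x - y)**2)."""
    xx, xy, _ = _dots(x, y)
    if xx == 0.0:
        raise ValueError("x is identically zero")
    return xy / xx


def ols_slope_horizontal(x, y) -> float:
    """Slope minimizing the horizontal squared error sum((x - y/alpha)**2)."""
    _, xy, yy = _dots(x, y)
    if xy == 0.0:
        raise OrthogonalColumnsError("x.y = 0: horizontal OLS slope undefined")
    return yy / xy


def gm_slope(x, y) -> float:
    """Geometric-mean (reduced-major-axis) slope +/- sqrt(y.y / x.x).

    The sign is that of x.y.  In magnitude this is the geometric mean of
    the vertical and horizontal OLS slopes, and it is the exact minimizer of
    the product error E(alpha) = E_x(alpha) * E_y(alpha).
    """
    xx, xy, yy = _dots(x, y)
    if xy == 0.0:
        raise OrthogonalColumnsError("x.y = 0: geometric-mean slope undefined")
    return math.copysign(math.sqrt(yy / xx), xy)


def area_slope(x, y) -> float:
    """Slope minimizing the summed triangle areas 0.5 * sum(d_i * h_i).

    d_i and h_i are the vertical and horizontal deviations; the objective is
    (alpha**2 x.x - 2 alpha x.y + y.y) / (2 |alpha|), whose stationary point
    satisfies alpha**2 = y.y / x.x — the geometric-mean slope again.
    """
    xx, xy, yy = _dots(x, y)
    if xy == 0.0:
        raise OrthogonalColumnsError("x.y = 0: least-area slope undefined")
    return math.copysign(math.sqrt(yy / xx), xy)


def distance_slope(x, y, s_x: float = 1.0, s_y: float = 1.0,
                   scaling: str | None = None) -> float:
    """Perpendicular-distance (principal-axis) slope.

    The data are nondimensionalized as X = x/S_x, Y = y/S_y (the distance
    error requires a dimensionless slope), the first principal axis is
    computed in the scaled coordinates,

        abar = (-lam + sign(X.Y) * sqrt(lam**2 + 4)) / 2,
        lam = (X.X - Y.Y) / (X.Y),

    and the slope is mapped back as alpha = abar * S_y / S_x.  This slope is
    rotation invariant only when unscaled (S_x = S_y = 1); it is never scale
    invariant.

    ``scaling`` overrides (s_x, s_y) with a named convention: ``"max"``
    (infinity norm), ``"l2_sqrtn"`` (||.||_2 / sqrt(n)), ``"l1_n"``
    (||.||_1 / n) or ``"none"``.
    """
    x, y = _vec(x), _vec(y)
    if scaling is not None:
        if scaling not in SCALINGS:
            raise ValueError(f"unknown scaling {scaling!r}; choose from {SCALINGS}")
        n = x.size
        if scaling == "none":
            s_x = s_y = 1.0
        elif scaling == "max":
            s_x, s_y = np.abs(x).max(), np.abs(y).max()
        elif scaling == "l2_sqrtn":
            s_x, s_y = np.linalg.norm(x) / math.sqrt(n), np.linalg.norm(y) / math.sqrt(n)
        else:
            s_x, s_y = np.abs(x).sum() / n, np.abs(y).sum() / n
    if s_x <= 0 or s_y <= 0:
        raise ValueError("scale factors must be positive")
    X, Y = x / s_x, y / s_y
    XX, XY, YY = _dots(X, Y)
    if XY == 0.0:
        raise OrthogonalColumnsError("X.Y = 0: distance slope sign rule undefined")
    lam = (XX - YY) / XY
    abar = 0.5 * (-lam + math.copysign(math.sqrt(lam * lam + 4.0), XY))
    return abar * s_y / s_x


def cf_bivariate(x, y) -> float:
    """Goodness-of-fit statistic C_F = (1 - |R|) / (2 (1 + |R|)) in [0, 1/2).

    Measures how far the geometric-mean slope sits from the midpoint of the
    two OLS slopes, relative to their separation.  0 for perfectly collinear
    data; approaches 1/2 as the correlation vanishes.
    """
    xx, xy, yy = _dots(x, y)
    if xy == 0.0:
        raise OrthogonalColumnsError("x.y = 0: C_F undefined")
    r = xy / math.sqrt(xx * yy)
    r = max(-1.0, min(1.0, r))
    if abs(abs(r) - 1.0) < 1e-15:
        return 0.0  # collinear: the ratio form is 0/0; the closed form's limit is 0
    return 0.5 * (1.0 - abs(r)) / (1.0 + abs(r))


@dataclass(frozen=True)
class BivariateFit:
    """A fitted two-variable slope with its fit statistic."""

    slope: float
    method: str
    r: float
    cf: float


def fit_bivariate(x, y, method: str = "geometric_mean", **kwargs) -> BivariateFit:
    """Fit ``y = alpha * x`` by the named method and attach R and C_F."""
    methods = {
        "vertical": ols_slope_vertical,
        "horizontal": ols_slope_horizontal,
        "geometric_mean": gm_slope,
        "distance": distance_slope,
        "area": area_slope,
    }
    if method not in methods:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(methods)}")
    slope = methods[method](x, y, **kwargs)
    xx, xy, yy = _dots(x, y)
    r = xy / math.sqrt(xx * yy)
    return BivariateFit(slope=slope, method=method, r=r, cf=cf_bivariate(x, y))


@dataclass(frozen=True)
class InvarianceReport:
    """Maximal residuals of the scale- and rotation-invariance relations.

    ``gm_scale_residual``      — geometric-mean slope vs the scale relation
                                 alpha(x,y) = (S_y/S_x) alpha(x/S_x, y/S_y)
    ``gm_rotation_residual``   — geometric-mean slope vs the rotation relation
                                 alpha' = (a cos t - sin t)/(a sin t + cos t)
    ``distance_rotation_residual`` — unscaled distance slope vs the same
                                 rotation relation (satisfied)
    """

    gm_scale_residual: float
    gm_rotation_residual: float
    distance_rotation_residual: float


def _rotation_predicted(alpha: float, theta: float) -> float:
    c, s = math.cos(theta), math.sin(theta)
    return (alpha * c - s) / (alpha * s + c)


def invariance_demo(x, y, scalings, angle: float) -> InvarianceReport:
    """Demonstrate that scale and rotational invariance are incompatible.

    For each positive scaling pair the geometric-mean slope is shown to obey
    the scale relation exactly; under a rotation by ``angle`` it violates
    the rotation relation on generic (non-collinear) data, while the
    unscaled perpendicular-distance slope satisfies it.
    """
    x, y = _vec(x), _vec(y)
    a_gm = gm_slope(x, y)
    scale_res = 0.0
    for s_x, s_y in scalings:
        if s_x <= 0 or s_y <= 0:
            raise ValueError("scalings must be positive")
        scale_res = max(
            scale_res, abs(a_gm - (s_y / s_x) * gm_slope(x / s_x, y / s_y))
        )
    c, s = math.cos(angle), math.sin(angle)
    xr = c * x + s * y
    yr = -s * x + c * y
    gm_rot = abs(gm_slope(xr, yr) - _rotation_predicted(a_gm, angle))
    a_d = distance_slope(x, y)
    d_rot = abs(distance_slope(xr, yr) - _rotation_predicted(a_d, angle))
    return InvarianceReport(
        gm_scale_residual=scale_res,
        gm_rotation_residual=gm_rot,
        distance_rotation_residual=d_rot,
    )
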