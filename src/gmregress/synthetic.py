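"""Synthetic point clouds near lines, hyperplanes and structured perturbations.

These generators produce the simulation inputs used throughout the test
suite and the worked examples: points scattered uniformly along a true
subspace with uniform perpendicular offsets bounded by an exact noise
radius, and structured perturbations P = P0 + eps * P1 (P0 exactly on the
subspace, P1 fixed) for studying the order of the centroid approximation.

All generated tables have exactly zero column means (the fits assume
centered, no-intercept data) *and* every point lies within ``noise_radius``
of the true subspace: after centering, the perpendicular offsets are
shrunk by a common factor min(1, r / max ||offset||) so the distance bound
holds exactly.  The same integer seed always reproduces the same table;
when a draw happens to violate the no-orthogonal-columns assumption it is
regenerated from the next substream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import DataMatrix

__all__ = [
    "SyntheticSpec",
    "points_near_line",
    "points_near_hyperplane",
    "StructuredPerturbation",
    "structured_perturbation",
    "transform",
]

logger = logging.getLogger(__name__)

_MAX_REGEN = 16


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    ``true_coefficients`` are (a_2, ..., a_m) for a line (direction
    (1, a_2, ..., a_m)) or (a_1, ..., a_{m-1}) for a hyperplane
    (p_m = sum a_j p_j).  ``noise_radius`` bounds the exact perpendicular
    distance of every point from the subspace; ``extent`` is the half-width
    of the uniform spread along the subspace.
    """

    kind: str
    true_coefficients: tuple[float, ...]
    n: int
    noise_radius: float
    seed: int
    extent: float = 1.0

    def __post_init__(self):
        if self.kind not in ("line", "hyperplane", "structured_perturbation"):
            raise ValueError(f"unknown kind {self.kind!r}")
        object.__setattr__(
            self, "true_coefficients", tuple(float(c) for c in self.true_coefficients)
        )
        if self.noise_radius < 0:
            raise ValueError("noise_radius must be nonnegative")
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        if self.n < 2:
            raise ValueError("need at least two points")


def _names(m: int) -> tuple[str, ...]:
    return tuple(f"p{i + 1}" for i in range(m))


def _center_and_clip(offsets: np.ndarray, radius: float) -> np.ndarray:
    """Zero-mean offsets within ``radius`` exactly (common shrink factor)."""
    offsets = offsets - offsets.mean(axis=0)
    if radius == 0.0:
        return np.zeros_like(offsets)
    norms = np.linalg.norm(offsets, axis=1) if offsets.ndim == 2 else np.abs(offsets)
    peak = float(norms.max())
    if peak > radius:
        offsets = offsets * (radius / peak)
    return offsets


def _nonorthogonal(values: np.ndarray) -> bool:
    norms = np.linalg.norm(values, axis=0)
    if np.any(norms == 0.0):
        return False
    cos = values.T @ values / np.outer(norms, norms)
    np.fill_diagonal(cos, 1.0)
    return bool(np.all(np.abs(cos) > 1e-8))


def _generate(spec: SyntheticSpec, draw) -> DataMatrix:
    for attempt in range(_MAX_REGEN):
        rng = np.random.default_rng([spec.seed, attempt])
        values = draw(rng)
        if _nonorthogonal(values):
            if attempt:
                logger.info(
                    "regenerated %s data %d time(s) to avoid orthogonal columns",
                    spec.kind, attempt,
                )
            return DataMatrix(
                values=values, variable_names=_names(values.shape[1]), centered=True
            )
    raise RuntimeError("could not draw data satisfying the nonorthogonality check")


def points_near_line(spec: SyntheticSpec) -> DataMatrix:
    """n centered points within ``noise_radius`` of the line (1, a_2, .., a_m).

    The line is parameterized by the reference variable: a point on it is
    t * (1, a_2, ..., a_m) with t uniform on (-extent, extent), matching
    the hyperplane generator where the independent coordinates are spread
    over the extent.  Perpendicular offsets are uniform in the (m-1)-ball
    of radius ``noise_radius``.
    """
    if spec.kind != "line":
        raise ValueError("spec.kind must be 'line'")
    direction = np.concatenate(([1.0], spec.true_coefficients))
    m = direction.size
    v_hat = direction / np.linalg.norm(direction)
    # orthonormal basis of the perpendicular complement
    q, _ = np.linalg.qr(np.column_stack([v_hat, np.eye(m)[:, : m - 1]]))
    perp = q[:, 1:]

    def draw(rng: np.random.Generator) -> np.ndarray:
        t = rng.uniform(-spec.extent, spec.extent, size=spec.n)
        t = (t - t.mean()) * np.linalg.norm(direction)
        g = rng.standard_normal((spec.n, m - 1))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        radii = spec.noise_radius * rng.uniform(0, 1, spec.n) ** (1.0 / (m - 1))
        coords = _center_and_clip(g * radii[:, None], spec.noise_radius)
        return np.outer(t, v_hat) + coords @ perp.T

    return _generate(spec, draw)


def points_near_hyperplane(spec: SyntheticSpec) -> DataMatrix:
    """n centered points within ``noise_radius`` of p_m = sum a_j p_j.

    In-plane coordinates are uniform on (-extent, extent)^(m-1); the signed
    offset along the unit normal is uniform on (-noise_radius, noise_radius).
    """
    if spec.kind != "hyperplane":
        raise ValueError("spec.kind must be 'hyperplane'")
    coeffs = np.asarray(spec.true_coefficients, dtype=float)
    m = coeffs.size + 1
    normal = np.concatenate((coeffs, [-1.0]))
    n_hat = normal / np.linalg.norm(normal)
    basis = np.vstack([np.eye(m - 1), coeffs]).T  # rows: e_j + a_j e_m

    def draw(rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(-spec.extent, spec.extent, size=(spec.n, m - 1))
        u = u - u.mean(axis=0)
        d = rng.uniform(-spec.noise_radius, spec.noise_radius, size=spec.n)
        d = _center_and_clip(d, spec.noise_radius)
        return u @ basis + np.outer(d, n_hat)

    return _generate(spec, draw)


@dataclass(frozen=True)
class StructuredPerturbation:
    """The pair (P0, P1) behind the expansion P = P0 + eps * P1.

    ``P0`` lies exactly on the stated subspace and ``P1`` is a fixed,
    column-centered, unit-column-norm perturbation; both are shared across
    every ``eps``, so d(eps) = ||minimizer - centroid|| can be measured on
    a common structure.
    """

    P0: np.ndarray
    P1: np.ndarray
    variable_names: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.variable_names is None:
            object.__setattr__(self, "variable_names", _names(self.P0.shape[1]))

    def at(self, eps: float) -> DataMatrix:
        return DataMatrix(
            values=self.P0 + eps * self.P1,
            variable_names=self.variable_names,
            centered=True,
        )


def structured_perturbation(spec: SyntheticSpec) -> StructuredPerturbation:
    """Build (P0, P1) for the centroid-order experiments.

    ``spec.kind`` selects whether P0 lies on a line or a hyperplane with
    ``spec.true_coefficients``; ``noise_radius`` is ignored (the
    perturbation size is the caller's ``eps``).
    """
    exact = SyntheticSpec(
        kind="line" if spec.kind != "hyperplane" else "hyperplane",
        true_coefficients=spec.true_coefficients,
        n=spec.n,
        noise_radius=0.0,
        seed=spec.seed,
        extent=spec.extent,
    )
    if exact.kind == "line":
        P0 = points_near_line(exact).values
    else:
        P0 = points_near_hyperplane(exact).values
    rng = np.random.default_rng([spec.seed, 10_007])
    P1 = rng.standard_normal(P0.shape)
    P1 -= P1.mean(axis=0)
    P1 /= np.linalg.norm(P1, axis=0)
    return StructuredPerturbation(P0=P0, P1=P1)


def transform(data: DataMatrix, action) -> DataMatrix:
    """Apply a named transformation to a centered table.

    ``action`` is one of

    * ``("scale", s)`` — positive diagonal scaling by the m-vector ``s``
    * ``("rotate", Q)`` — orthogonal rotation mixing the variables
    * ``("permute", perm)`` — column relabeling

    The result stays centered; names follow permutations.
    """
    kind, arg = action
    V = data.values
    if kind == "scale":
        s = np.asarray(arg, dtype=float).ravel()
        if s.size != data.m or np.any(s <= 0):
            raise ValueError("scaling requires m positive factors")
        return DataMatrix(V * s, data.variable_names,
                          column_means=data.column_means * s, centered=data.centered)
    if kind == "rotate":
        Q = np.asarray(arg, dtype=float)
        if Q.shape != (data.m, data.m) or not np.allclose(Q @ Q.T, np.eye(data.m),
                                                          atol=1e-10):
            raise ValueError("rotation requires an m x m orthogonal matrix")
        return DataMatrix(V @ Q.T, data.variable_names,
                          column_means=Q @ data.column_means, centered=data.centered)
    if kind == "permute":
        perm = list(arg)
        if sorted(perm) != list(range(data.m)):
            raise ValueError("permutation must rearrange all column indices")
        return DataMatrix(V[:, perm],
                          tuple(data.variable_names[i] for i in perm),
                          column_means=data.column_means[perm],
                          centered=data.centered)
    raise ValueError(f"unknown action {kind!r}")
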