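"""Observation tables, centering and train/test splitting.

All of the regression machinery in this package operates on *centered*
columns: every model is a linear subspace through the origin, so the column
means are removed first and retained for mapping predictions back to the
original units.  ``DataMatrix`` is the shared container; it is a thin wrapper
around an ``n x m`` :class:`numpy.ndarray` with column names, the stored
column means and a ``centered`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "SplitSpec",
    "read_table",
    "write_table",
    "center",
    "split",
]


class DegenerateColumnError(ValueError):
    """A column is constant (zero variance after centering)."""


class OrthogonalColumnsError(ValueError):
    """Two centered columns are (numerically) orthogonal.

    The geometric-mean error functions assume no two centered data vectors
    are orthogonal; the closed-form simplex vertices divide by the pairwise
    dot products.
    """


class InsufficientDataError(ValueError):
    """Fewer observations than the fit requires (n < m + 1)."""


@dataclass(frozen=True)
class DataMatrix:
    """A numeric observation table: rows are observations, columns variables.

    Parameters
    ----------
    values : (n, m) ndarray
        The observations.  Unitless once centered.
    variable_names : tuple of str
        One label per column.
    column_means : (m,) ndarray
        Means subtracted during centering (original units); zeros while the
        table is uncentered.
    centered : bool
        Whether :func:`center` has been applied.
    """

    values: np.ndarray
    variable_names: tuple[str, ...]
    column_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    centered: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-d array (rows=observations)")
        object.__setattr__(self, "values", values)
        if self.column_means is None:
            object.__setattr__(self, "column_means", np.zeros(values.shape[1]))
        else:
            object.__setattr__(
                self, "column_means", np.asarray(self.column_means, dtype=float)
            )
        if len(self.variable_names) != values.shape[1]:
            raise ValueError("one name per column required")
        if self.centered:
            scale = np.maximum(np.abs(values).max(axis=0, initial=0.0), 1.0)
            sums = np.abs(values.sum(axis=0))
            if np.any(sums > 1e-9 * values.shape[0] * scale):
                raise ValueError("centered flag set but column sums are nonzero")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def column(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            name_or_index = self.variable_names.index(name_or_index)
        return self.values[:, name_or_index]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.variable_names))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, centered: bool = False) -> "DataMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            variable_names=tuple(str(c) for c in df.columns),
            centered=centered,
        )

    def require_fit_ready(self) -> None:
        """Validate the standing assumptions of the subspace fits.

        Centered data, n >= m + 1, no identically-zero column, and no two
        columns orthogonal (the error-simplex vertices divide by pairwise
        dot products).
        """
        if not self.centered:
            raise ValueError("fitting requires centered data; call center() first")
        if self.n < self.m + 1:
            raise InsufficientDataError(
                f"need at least m+1={self.m + 1} observations, got {self.n}"
            )
        norms = np.linalg.norm(self.values, axis=0)
        if np.any(norms == 0.0):
            j = int(np.argmin(norms))
            raise DegenerateColumnError(
                f"column {self.variable_names[j]!r} is identically zero"
            )
        gram = self.values.T @ self.values
        off = gram / np.outer(norms, norms)
        np.fill_diagonal(off, 1.0)
        if np.any(np.abs(off) < 1e-12):
            i, j = np.unravel_index(np.argmin(np.abs(off)), off.shape)
            raise OrthogonalColumnsError(
                f"columns {self.variable_names[i]!r} and {self.variable_names[j]!r}"
                " are orthogonal; the geometric-mean error is undefined"
            )


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition parameters."""

    train_fraction: float
    seed: int

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def read_table(path, delimiter: str = ",", has_header: bool = True) -> DataMatrix:
    """Read a delimited numeric table into an uncentered :class:`DataMatrix`.

    Non-numeric cells and ragged rows raise ``ValueError`` naming the
    offending location.
    """
    header = 0 if has_header else None
    try:
        df = pd.read_csv(path, delimiter=delimiter, header=header)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    if not has_header:
        df.columns = [f"v{i + 1}" for i in range(df.shape[1])]
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            mask = numeric.isna() | bad
            row = int(np.argmax(mask.to_numpy()))
            raise ValueError(
                f"non-numeric cell at row {row}, column {col!r} in {path}"
            )
        df[col] = numeric
    return DataMatrix.from_dataframe(df)


def write_table(data: DataMatrix, path, delimiter: str = ",") -> None:
    data.to_dataframe().to_csv(path, sep=delimiter, index=False)


def center(data: DataMatrix) -> DataMatrix:
    """Subtract column means, storing them on the result.

    Raises if the table is already centered (double-centering would silently
    discard the original means) or if a column is constant.
    """
    if data.centered:
        raise ValueError("data are already centered")
    means = data.values.mean(axis=0)
    centered_values = data.values - means
    spans = np.abs(centered_values).max(axis=0, initial=0.0)
    if np.any(spans == 0.0):
        j = int(np.argmin(spans))
        raise DegenerateColumnError(
            f"column {data.variable_names[j]!r} has identical values"
        )
    return DataMatrix(
        values=centered_values,
        variable_names=data.variable_names,
        column_means=means,
        centered=True,
    )


def center_like(test: DataMatrix, train: DataMatrix) -> DataMatrix:
    """Center ``test`` with the *training* column means.

    Test residuals are computed against the training origin, matching the
    no-intercept model fitted on the centered training set.
    """
    if test.centered:
        raise ValueError("test data are already centered")
    return DataMatrix(
        values=test.values - train.column_means,
        variable_names=test.variable_names,
        column_means=train.column_means,
        centered=False,  # means are the training ones; column sums need not vanish
    )


def split(data: DataMatrix, spec: SplitSpec) -> tuple[DataMatrix, DataMatrix]:
    """Randomly partition rows into train and test sets.

    The partition is reproducible under ``spec.seed`` and centering is left
    to the caller: the training means are the ones subtracted from both
    pieces downstream.
    """
    if data.centered:
        raise ValueError("split uncentered data; center the training set after")
    n_train = int(round(spec.train_fraction * data.n))
    if n_train < data.m + 1:
        raise InsufficientDataError(
            f"train_fraction {spec.train_fraction} leaves {n_train} rows; "
            f"need at least {data.m + 1}"
        )
    if n_train >= data.n:
        raise InsufficientDataError("train_fraction leaves an empty test set")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(data.n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    make = lambda idx: DataMatrix(  # noqa: E731
        values=data.values[idx],
        variable_names=data.variable_names,
        centered=False,
    )
    return make(train_idx), make(test_idx)
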