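import numpy as np
import pytest

from gmregress import DataMatrix, SyntheticSpec, points_near_hyperplane, points_near_line


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def line_data():
    """40 points within perpendicular distance 0.2 of the line a2=3, a3=5."""
    return points_near_line(
        SyntheticSpec(kind="line", true_coefficients=(3, 5), n=40,
                      noise_radius=0.2, seed=1)
    )


@pytest.fixture
def plane_data():
    """40 points within distance 0.15 of the plane z = -10x + 6y."""
    return points_near_hyperplane(
        SyntheticSpec(kind="hyperplane", true_coefficients=(-10, 6), n=40,
                      noise_radius=0.15, seed=2)
    )


def make_centered(values, names=None) -> DataMatrix:
    values = np.asarray(values, dtype=float)
    values = values - values.mean(axis=0)
    names = names or tuple(f"p{i + 1}" for i in range(values.shape[1]))
    return DataMatrix(values=values, variable_names=tuple(names), centered=True)


@pytest.fixture
def make_centered_matrix():
    return make_centered
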