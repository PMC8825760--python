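import numpy as np
import pytest


def distance_matrix_from_points(points: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix from an n x d (or 1-D) point array."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


@pytest.fixture
def dmat_1d():
    return distance_matrix_from_points


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
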