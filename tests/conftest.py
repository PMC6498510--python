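import numpy as np
import pytest

from focusmds import validate_distance_matrix
from focusmds.synthetic import planted_2d


@pytest.fixture
def rectangle_dm():
    """Corners of a 3 x 4 rectangle: a configuration exactly embeddable in 2-D."""
    pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0], [3.0, 4.0]])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return validate_distance_matrix(d, ["A", "B", "C", "D"]), pts


@pytest.fixture
def small_planted():
    cfg, dm = planted_2d(10, seed=42)
    return cfg, dm


def random_symmetric_dm(n, rng):
    """Random positive symmetric matrix with zero diagonal (not necessarily metric)."""
    m = rng.uniform(0.5, 10.0, size=(n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return validate_distance_matrix(m)
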