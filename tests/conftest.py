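import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from codac.graph import Bigraph

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_bigraph(
    rng: np.random.Generator,
    n_left: int,
    n_right: int,
    density: float,
    left_prefix: str = "l",
    right_prefix: str = "r",
) -> Bigraph:
    """Erdős–Rényi style bipartite graph with full vocabularies."""
    left = tuple(f"{left_prefix}{i}" for i in range(n_left))
    right = tuple(f"{right_prefix}{j}" for j in range(n_right))
    mask = rng.random((n_left, n_right)) < density
    edges = frozenset((left[i], right[j]) for i, j in np.argwhere(mask))
    return Bigraph(left, right, edges)


def random_bigraph_pair(
    rng: np.random.Generator, n_x: int, n_y: int, n_z: int, density: float
) -> tuple[Bigraph, Bigraph]:
    """X–Z and Y–Z layers over a shared Z vocabulary."""
    g1 = random_bigraph(rng, n_x, n_z, density, "x", "z")
    g2 = random_bigraph(rng, n_y, n_z, density, "y", "z")
    return g1, g2


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
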