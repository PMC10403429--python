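import numpy as np
import pytest

from netsgcca import PriorGraph, SyntheticSpec, simulate_two_block
from netsgcca.blocks import Block
from netsgcca.model import SolverSettings


@pytest.fixture
def p3_graph() -> PriorGraph:
    """Path graph g1 - g2 - g3."""
    return PriorGraph.from_edges(["g1", "g2", "g3"], [("g1", "g2"), ("g2", "g3")])


@pytest.fixture(scope="session")
def synth_ds():
    """The default synthetic two-block dataset (n=100, p1=200, community
    graph, 10-feature support on one community)."""
    return simulate_two_block(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def fast_settings() -> SolverSettings:
    """Reduced iteration caps for experiment-scale fits; the Dykstra
    tolerance stays at its default so feasibility is preserved."""
    return SolverSettings(outer_tol=1e-5, outer_max_iter=60,
                          inner_max_iter=40, inner_tol=1e-7)


def random_blocks(seed: int, n: int = 20, J: int = 2, p_max: int = 15,
                  shared_signal: float = 1.0):
    """Small random paired blocks with a shared latent factor."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n)
    blocks = []
    for j in range(J):
        p = int(rng.integers(3, p_max + 1))
        X = (shared_signal * u[:, None] * rng.uniform(0.3, 1.5, p)
             + rng.standard_normal((n, p)))
        blocks.append(Block(
            name=f"b{j}", matrix=X,
            feature_names=[f"b{j}f{i}" for i in range(p)],
            sample_ids=[f"s{i}" for i in range(n)],
        ))
    return blocks
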