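import numpy as np
import pytest

from slossgen import SimulationConfig, simulate_island_system


@pytest.fixture(scope="session")
def default_system():
    """One default-condition synthetic archipelago, shared across tests."""
    return simulate_island_system(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_view(default_system):
    """Collapsed haplotypes + matching consensus tree for the shared system."""
    return default_system.consensus_view()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_tree_newick(rng, n_tips):
    """Random rooted binary tree with exponential branch lengths (newick)."""
    nodes = [f"T{i}:{rng.exponential(0.5):.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(0.5):.6f}")
    inner = nodes[0].rsplit(":", 1)[0]
    return inner + ";"
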