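import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mcpgraph as mg

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def hierarchical():
    """Two doses, primary/secondary endpoint hierarchy; weights (.5,.5,0,0)."""
    return mg.make_standard_graph("hierarchical")


@pytest.fixture
def block_corr():
    """rho=0.5 known within {H1,H2} and {H3,H4}; cross-pairs unknown."""
    corr = np.full((4, 4), np.nan)
    np.fill_diagonal(corr, 1.0)
    corr[0, 1] = corr[1, 0] = corr[2, 3] = corr[3, 2] = 0.5
    return mg.CorrelationModel(corr)


@pytest.fixture
def holm3():
    return mg.make_standard_graph("holm", m=3)


def random_graph(rng, m, exhaustive=False):
    """A random valid graph; with exhaustive=True all weight mass is kept."""
    w = rng.dirichlet(np.ones(m))
    if not exhaustive:
        w = w * rng.uniform(0.2, 1.0)
    g = np.zeros((m, m))
    for i in range(m):
        row = rng.dirichlet(np.ones(m - 1))
        if not exhaustive:
            row = row * rng.uniform(0.0, 1.0)
        g[i, [j for j in range(m) if j != i]] = row
    return mg.new_graph([f"H{i+1}" for i in range(m)], w, g)


def random_pvalues(rng, m):
    """Mixture of uniform and small p-values so rejections actually occur."""
    p = rng.uniform(size=m)
    small = rng.random(m) < 0.5
    p[small] = rng.uniform(0.0, 0.1, size=small.sum())
    return p
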