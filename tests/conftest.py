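import numpy as np
import pandas as pd
import pytest

import tilp


@pytest.fixture(scope="session")
def mcf7_map():
    return tilp.load_mcf7_map()


@pytest.fixture(scope="session")
def mcf7_profile(mcf7_map):
    """A deterministic 10-condition ternary profile over the observed nodes."""
    rng = np.random.default_rng(42)
    observed = [n.id for n in mcf7_map.observed_nodes]
    conds = [f"c{i}" for i in range(10)]
    values = rng.integers(-1, 2, size=(len(observed), len(conds))).astype(float)
    return tilp.TernaryProfile(pd.DataFrame(values, index=observed, columns=conds))


def random_small_instance(seed):
    """Random instance inside the oracle's enumeration bounds.

    3-6 signaling nodes, edge density 0.3-0.6 capped at 7 edges, 30%
    inhibitions, 1-2 conditions, 60-100% observation coverage, ~15%
    missing entries.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 7))
    density = rng.uniform(0.3, 0.6)
    names = [f"N{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density and len(edges) < 7:
                sign = -1 if rng.random() < 0.3 else 1
                edges.append((names[i], sign, names[j]))
    if not edges:
        edges = [(names[0], 1, names[-1])]
    coverage = rng.uniform(0.6, 1.0)
    observed = [nm for nm in names if rng.random() < coverage] or [names[0]]
    net = tilp.build_network(edges, observed=observed)
    n_cond = int(rng.integers(1, 3))
    conds = [f"k{c}" for c in range(n_cond)]
    values = rng.integers(-1, 2, size=(len(observed), n_cond)).astype(float)
    values[rng.random(values.shape) < 0.15] = np.nan
    profile = tilp.TernaryProfile(pd.DataFrame(values, index=observed, columns=conds))
    return net, profile


@pytest.fixture
def toy_chain():
    """A -> B activation with both endpoints observed."""
    return tilp.build_network([("A", 1, "B")], observed=["A", "B"])
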