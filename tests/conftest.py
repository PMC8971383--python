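import random

import numpy as np
import pandas as pd
import pytest

from paleobrain.synthetic import SimulationConfig, simulate_dataset
from paleobrain.trees import parse_newick


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def fossil_tree():
    return parse_newick("((A:1,B:0.5):1,C:2);")


@pytest.fixture(scope="session")
def default_dataset():
    """One study-sized synthetic dataset shared across tests."""
    return simulate_dataset(SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SimulationConfig(seed=77, n_tips=80))


def random_bd_tree(n_tips: int, seed: int, death_rate: float = 0.25):
    """Small birth-death tree helper for oracle tests."""
    cfg = SimulationConfig(seed=seed, n_tips=n_tips, death_rate=death_rate)
    from paleobrain.synthetic import simulate_tree

    return simulate_tree(cfg, rng=random.Random(seed))


def random_trait_frame(tree, seed: int) -> pd.DataFrame:
    """Trait frame with both statuses, aligned to a tree's tips."""
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    body = rng.uniform(0.2, 4.0, n)
    endo = 0.9 + 0.75 * body + rng.normal(0, 0.25, n)
    status = np.array(["extant"] * n, dtype=object)
    status[rng.choice(n, size=max(2, n // 5), replace=False)] = "extinct"
    return pd.DataFrame(
        {
            "species": tree.tip_labels,
            "order": ["o1"] * n,
            "status": status,
            "log10_body": body,
            "log10_endocast": endo,
        }
    )
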