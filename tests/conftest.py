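from __future__ import annotations

import numpy as np
import pytest

from commphylo import SynthConfig, generate_tree, parse_newick

BALANCED4 = "((A:1,B:1):1,(C:1,D:1):1);"
STAR3 = "(A:1,B:1,C:1);"


@pytest.fixture
def tree4():
    """The four-tip balanced tree used throughout the examples."""
    return parse_newick(BALANCED4)


@pytest.fixture
def star3():
    return parse_newick(STAR3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


def random_tree(n_tips: int, seed: int):
    """Seeded Yule tree helper shared by several test modules."""
    cfg = SynthConfig(
        n_tips=n_tips, richness_range=(1, min(5, n_tips)), seed=seed
    )
    return generate_tree(cfg)
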