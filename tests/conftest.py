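"""Shared fixtures: small hand-built tables/trees and mid-size simulations."""

import numpy as np
import pytest
from skbio import TreeNode

import recoverymics as r
from recoverymics.core_io import CountTable


@pytest.fixture
def tiny_table():
    return CountTable(["s1", "s2"], ["a", "b"], np.array([[5, 0], [1, 3]]))


@pytest.fixture
def star_tree4():
    """Four leaves attached directly to the root, unit branch lengths."""
    return TreeNode.read(["(A:1,B:1,C:1,D:1);"])


@pytest.fixture
def paired_tree4():
    return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])


@pytest.fixture(scope="session")
def lognormal_pool():
    return r.make_source_pool(150, "lognormal", {"sigma": 1.5}, seed=1)


@pytest.fixture(scope="session")
def neutral_stationary_table(lognormal_pool):
    """Mid-size neutral community batch used by several fitting tests."""
    cfg = r.SimulationConfig(
        n_samples=200, N_local=1000, m=0.3, depth=2000, mode="stationary", seed=5
    )
    return r.simulate_neutral_community(lognormal_pool, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
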