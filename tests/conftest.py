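import random

import pytest

from nlrdiv import SimConfig, read_tree, simulate_nlrome


def random_newick(rng: random.Random, n_leaves: int,
                  blen=(0.01, 0.5), supports=(0, 50, 70, 95, 100),
                  p_missing_support=0.2) -> str:
    """Random rooted bifurcating Newick with branch lengths and supports.

    Supports are drawn from a small set so ties occur and tie-breaking
    rules are actually exercised.
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    rng.shuffle(labels)

    def build(leaves):
        if len(leaves) == 1:
            return f"{leaves[0]}:{rng.uniform(*blen):.4f}"
        k = rng.randint(1, len(leaves) - 1)
        left, right = leaves[:k], leaves[k:]
        sup = "" if rng.random() < p_missing_support else str(rng.choice(supports))
        return (
            f"({build(left)},{build(right)}){sup}:{rng.uniform(*blen):.4f}"
        )

    k = rng.randint(1, n_leaves - 1)
    return f"({build(labels[:k])},{build(labels[k:])});"


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated NLRome shared by read-only tests."""
    cfg = SimConfig(seed=7, n_ecotypes=12, n_families=6, repeat_count=8,
                    n_hv_columns=12, hv_family_fraction=1 / 3)
    tree, alignments, truth = simulate_nlrome(cfg)
    return cfg, tree, alignments, truth


def tree_from_newick(newick: str):
    return read_tree(data=newick)
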