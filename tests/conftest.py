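import numpy as np
import pytest

import gmycdelim as g


@pytest.fixture
def three_tip_tree():
    return g.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    return g.parse_newick("((A:.1,B:.1):.9,(C:.2,D:.2):.8);")


@pytest.fixture(scope="session")
def small_tree_pool():
    """Seeded pool of small trees (3-6 tips) for oracle/property checks."""
    trees = []
    for seed in range(1, 101):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        trees.append(g.simulate_null_tree(n, 1.0, seed=seed))
    for seed in range(1, 101):
        rng = np.random.default_rng(1000 + seed)
        k = int(rng.integers(2, 4))
        sizes = [int(rng.integers(1, 4)) for _ in range(k)]
        if sum(sizes) < 3:
            sizes[0] += 2
        tree, _ = g.simulate_mixed_tree(k, 1.0, sizes, 50.0, seed=1000 + seed)
        trees.append(tree)
    return trees


@pytest.fixture(scope="session")
def recovery_fits():
    """Single-threshold fits on 20 simulated 10-species trees (seeds 1-20)."""
    fits = []
    for seed in range(1, 21):
        tree, truth = g.simulate_mixed_tree(10, 1.0, 10, 200.0, seed=seed)
        fits.append((g.fit_single_threshold(tree), truth))
    return fits
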