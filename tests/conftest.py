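import pytest

from rxntrees import (
    build_count_index,
    build_trees,
    bundled_examples,
    cluster_trees,
    default_benchmark,
)


@pytest.fixture(scope="session")
def bundled():
    """(catalog, reactions, rpairs) for the six fixed worked examples."""
    return bundled_examples()


@pytest.fixture(scope="session")
def bundled_trees(bundled):
    catalog, reactions, _ = bundled
    index = build_count_index(reactions, catalog)
    trees = build_trees(reactions, catalog, index)
    return {t.reaction_id: t for t in trees}


@pytest.fixture(scope="session")
def benchmark():
    """The separation-guaranteed synthetic benchmark (seed 42, n=500)."""
    universe, reactions, truth = default_benchmark(seed=42, n=500)
    trees = build_trees(reactions, universe.catalog)
    return universe, reactions, truth, trees


@pytest.fixture(scope="session")
def benchmark_clusters(benchmark):
    _, _, _, trees = benchmark
    return cluster_trees(trees)
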