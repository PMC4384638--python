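import numpy as np
import pytest

from phylocomp import PhyloTree, parse_newick
from phylocomp.pipeline import AnalysisConfig, load_trait_table
from phylocomp.simulate import simulate_yule_tree


@pytest.fixture
def three_leaf_tree() -> PhyloTree:
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def two_leaf_tree() -> PhyloTree:
    return parse_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def study_config() -> AnalysisConfig:
    return AnalysisConfig.reproduction()


@pytest.fixture(scope="session")
def study_table(study_config):
    return load_trait_table(study_config.trait_table)


@pytest.fixture(scope="session")
def study_trees(study_config):
    return {
        name: PhyloTree.from_file(p) for name, p in study_config.tree_paths.items()
    }


def random_tree(seed: int, n_min: int = 3, n_max: int = 20) -> PhyloTree:
    """Seeded Yule tree with a seeded size, for property tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    return simulate_yule_tree(n, 1.0, seed=seed + 1)
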