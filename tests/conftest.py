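import random

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")

ACCEPTANCE_SEEDS = (42, 43, 44, 45, 46)


def _slim(result):
    """Keep only the report (the session caches five runs; dropping the
    simulation objects keeps memory flat)."""
    return result.report.report


@pytest.fixture(scope="session")
def default_reports():
    """Full default-scenario pipeline reports for the five acceptance seeds."""
    from ssapipe.pipeline import PipelineConfig, run

    return {seed: _slim(run(PipelineConfig(seed=seed, write_reads=False)))
            for seed in ACCEPTANCE_SEEDS}


@pytest.fixture(scope="session")
def default_report(default_reports):
    return default_reports[42]


@pytest.fixture(scope="session")
def null_report():
    from ssapipe.pipeline import PipelineConfig, run

    return _slim(run(PipelineConfig(seed=42, scenario="null", write_reads=False)))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_tree_and_distances(n_taxa: int, seed: int):
    """A random tree with positive branch lengths and its additive patristic
    distance matrix (the generating tree is the oracle)."""
    import dendropy
    from dendropy.simulate import treesim
    from skbio import DistanceMatrix

    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=tns, rng=random.Random(seed))
    for edge in tree.preorder_edge_iter():
        edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    mat = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(tns):
        for j, b in enumerate(tns):
            if i != j:
                mat[i, j] = pdm.patristic_distance(a, b)
    return tree, DistanceMatrix(mat, [t.label for t in tns])


@pytest.fixture(scope="session")
def additive_oracle():
    return random_tree_and_distances
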