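"""Shared fixtures: small hand-built hierarchies and the standard benchmark.

The expensive session fixtures (the ~100-protein default benchmark, its
feature table, and the ten-seed forest-vs-tree cross-validation runs) are
computed once and shared by the integration and acceptance tests.
"""

import numpy as np
import pytest

import foldrec as fr
from foldrec.features import FeatureConfig, featurize_dataset
from helpers import make_protein


@pytest.fixture
def tiny_proteins():
    """Four proteins: two families in one fold, plus an unrelated fold."""
    return [
        make_protein("pA", "ACDEFGHIKL", "fam1", "sf1", "fold1"),
        make_protein("pB", "ACDEFGHIKV", "fam1", "sf1", "fold1"),
        make_protein("pC", "MNPQRSTVWY", "fam2", "sf2", "fold1"),
        make_protein("pD", "WYACWYACWY", "fam3", "sf3", "fold2"),
    ]


@pytest.fixture
def tiny_dataset(tiny_proteins):
    return fr.BenchmarkDataset(
        proteins=tiny_proteins, pairs=fr.enumerate_pairs(tiny_proteins)
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """A fast 3-fold benchmark (~24 proteins) for end-to-end smoke tests."""
    cfg = fr.SynthConfig(
        seed=11,
        n_folds_struct=3,
        superfamilies_per_fold=2,
        families_per_superfamily=2,
        proteins_per_family=2,
        seq_length=40,
    )
    ds = fr.generate_benchmark(cfg)
    table = featurize_dataset(ds, FeatureConfig())
    return ds, table


@pytest.fixture(scope="session")
def default_benchmark():
    """The standard desk-size benchmark and its feature table."""
    cfg = fr.default_lindahl_like_config(seed=7)
    ds = fr.generate_benchmark(cfg)
    table = featurize_dataset(ds, FeatureConfig())
    return ds, table


@pytest.fixture(scope="session")
def ten_seed_runs(default_benchmark):
    """Forest (100 trees) vs single-tree CV at seeds 0..9 on the benchmark."""
    ds, table = default_benchmark
    p = len(fr.feature_names(FeatureConfig()))
    runs = []
    for seed in range(10):
        forest_res = fr.run_cross_validation(
            ds, table, fr.ForestParams(n_trees=100), seed=seed
        )
        tree_res = fr.run_cross_validation(
            ds,
            table,
            fr.ForestParams(
                n_trees=1, bootstrap=False, n_features_sampled=p
            ),
            seed=seed,
        )
        runs.append({"seed": seed, "forest": forest_res, "tree": tree_res})
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
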