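import numpy as np
import pandas as pd
import pytest

from vespine.comparative import Phylogeny, read_newick
from vespine.patrilines import ColonyGenotypes, Genotype
from vespine.synthetic_data import (
    ColonySimConfig,
    default_locus_panel,
    simulate_balanced_tree,
)


@pytest.fixture(scope="session")
def panel():
    """Six 8-allele microsatellite loci with fixed frequency spectra."""
    return default_locus_panel(n_loci=6, n_alleles=8, rng=np.random.default_rng(42))


@pytest.fixture
def toy_colony():
    """Hand-built 2-father colony: queen 100/104, fathers carry 108 and 112."""
    queen = Genotype({"L1": (100, 104), "L2": (200, 202)})
    workers = [
        ("w1", Genotype({"L1": (100, 108), "L2": (200, 210)})),
        ("w2", Genotype({"L1": (104, 108), "L2": (202, 210)})),
        ("w3", Genotype({"L1": (100, 112), "L2": (200, 212)})),
        ("w4", Genotype({"L1": (104, 112), "L2": (202, 212)})),
    ]
    return ColonyGenotypes(
        colony_id="T1", species="toy", workers=workers, queen=queen, queenright=True
    )


@pytest.fixture(scope="session")
def small_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree22():
    return simulate_balanced_tree(n_tips=22, seed=7)


def random_colony_config(rng, panel, max_workers=8):
    """A small random colony for oracle comparisons."""
    k = int(rng.integers(1, 5))
    n = int(rng.integers(max(2, k), max_workers + 1))
    shares = rng.dirichlet(np.ones(k))
    return ColonySimConfig(
        loci=panel,
        k_true=k,
        shares=shares.tolist(),
        n_workers=n,
        missing_prob=float(rng.choice([0.0, 0.05, 0.15])),
        seed=int(rng.integers(2**31)),
    )
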