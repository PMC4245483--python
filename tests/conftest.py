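import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from plastocmp.simulate import (
    RegionGenes,
    SimulationParams,
    evolve,
    generate_ancestor,
)

#: two-clade five-leaf tree used by the small simulation fixtures
SMALL_TREE = (
    "((A:0.0020,B:0.0012):0.0025,(C:0.0018,D:0.0010):0.0015,E:0.0200);"
)

CLADE_MAP_8 = {
    "TaxonA": "TaxonA",
    "TaxonB": "Australian",
    "O_meridionalis": "Australian",
    "O_sativa_japonica": "Asian",
    "O_sativa_indica": "Asian",
    "O_rufipogon": "Asian",
    "O_nivara": "Asian",
}


def small_sim_params(**overrides) -> SimulationParams:
    """A scaled-down quadripartite genome (~16.5 kb) with a handful of genes
    in every region; fast enough for per-test simulation."""
    defaults = dict(
        lsc_len=9000,
        ir_len=2500,
        ssc_len=1500,
        lsc_genes=RegionGenes(
            n_protein=6, protein_mean_len=400, n_protein_intron=1, n_trna=3
        ),
        ssc_genes=RegionGenes(n_protein=1, protein_mean_len=400),
        ir_genes=RegionGenes(
            n_protein=1, protein_mean_len=300, rrna_lengths=(400,)
        ),
        intron_mean_len=200,
        tree_newick=SMALL_TREE,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def small_params():
    return small_sim_params()


@pytest.fixture(scope="session")
def small_ancestor(small_params):
    return generate_ancestor(small_params, seed=11)


@pytest.fixture(scope="session")
def small_family(small_params, small_ancestor):
    ancestor, features = small_ancestor
    leaves, truth = evolve(ancestor, features, small_params, seed=23)
    return ancestor, features, leaves, truth


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=n))


def mutated_copy(seq: str, rng, n_sub=0, n_del=0, n_ins=0, indel_max=6) -> str:
    """Random point/indel mutations of a sequence (test-side helper)."""
    b = list(seq)
    for _ in range(n_sub):
        p = int(rng.integers(0, len(b)))
        b[p] = rng.choice([x for x in "ACGT" if x != b[p]])
    for _ in range(n_del):
        p = int(rng.integers(0, max(1, len(b) - indel_max)))
        del b[p : p + int(rng.integers(1, indel_max))]
    for _ in range(n_ins):
        p = int(rng.integers(0, len(b)))
        ins = "".join(rng.choice(np.array(list("ACGT")), size=int(rng.integers(1, indel_max))))
        b.insert(p, ins)
    return "".join(b)
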