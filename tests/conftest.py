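import numpy as np
import pytest

from orevo.simulate import GenomeParams, SimConfig, query_references, simulate_run
from orevo.trees import DatedSpeciesTree


@pytest.fixture(scope="session")
def two_species_tree() -> DatedSpeciesTree:
    return DatedSpeciesTree.from_newick("(A,B)20;")


@pytest.fixture(scope="session")
def small_sim(two_species_tree):
    """A compact two-species synthetic run shared across miner/classifier
    tests: 14 planted families, quarter pseudogenized, tenth truncated."""
    cfg = SimConfig(
        tree=two_species_tree, ancestral_family_count=14, default_rates=(0.0, 0.0),
        genome=GenomeParams(contig_count=10, contig_length=15_000, decoy_gpcr_count=2,
                            pseudogenization_fraction=0.25, truncation_fraction=0.10),
        mutation_rate=0.002, ogg_divergence=0.2,  # all genes within the
        # miner's >= 60%-identity detection contract
        seed=7,
    )
    genomes, truth, reference, content = simulate_run(cfg)
    return {"cfg": cfg, "genomes": genomes, "truth": truth, "reference": reference,
            "content": content, "queries": query_references(reference)}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
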