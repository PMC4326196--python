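import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle modules

from repliconpan.cluster import cluster_pipeline
from repliconpan.pangenome import classify_families
from repliconpan.simulate import OperonSpec, SimConfig, simulate_pangenome


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic pan-genome reused across test modules."""
    cfg = SimConfig(
        n_chromosomes=3,
        n_plasmids=2,
        n_chr_core=6,
        n_chr_distributed=8,
        n_chr_unique=10,
        n_pls_distributed=5,
        n_pls_unique=6,
        n_shared=8,
        operons=OperonSpec(n_shared_operons=3, n_single_shared=2, n_unshared=2),
        seed=11,
    )
    return simulate_pangenome(cfg)


@pytest.fixture(scope="session")
def small_cluster(small_sim):
    return cluster_pipeline(small_sim.genes)


@pytest.fixture(scope="session")
def small_partition(small_sim, small_cluster):
    return classify_families(small_cluster.families, small_sim.replicons)
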