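import numpy as np
import pandas as pd
import pytest

from intropipe.io_formats import GenotypeMatrix
from intropipe.topology_weighting import TaxonGroups, enumerate_topologies

FIVE_POPS = ("focal", "niloticus", "aureus", "mossambicus", "urolepis")


@pytest.fixture(scope="session")
def five_groups() -> TaxonGroups:
    return TaxonGroups(
        {pop: [f"{pop}_{i + 1}" for i in range(2)] for pop in FIVE_POPS}
    )


@pytest.fixture(scope="session")
def five_topologies(five_groups):
    return enumerate_topologies(five_groups)


def make_matrix(freq_patterns, pops=FIVE_POPS, seqid="LG1"):
    """GenotypeMatrix with one haploid-like sample per population.

    ``freq_patterns`` is a list of tuples of 0/1 per population; genotype
    code is 2 * value so population frequencies are exactly 0 or 1.
    """
    n = len(freq_patterns)
    sites = pd.DataFrame(
        {
            "seqid": seqid,
            "pos": np.arange(1, n + 1) * 10,
            "ref": "A",
            "alt": "T",
            "total_depth": 300,
            "is_indel": False,
            "is_biallelic": True,
            "dist_to_indel": GenotypeMatrix.NO_INDEL,
        }
    )
    geno = np.array([[2 * v for v in row] for row in freq_patterns], dtype=np.int8)
    samples = [f"{p}_1" for p in pops]
    return GenotypeMatrix(
        sites=sites,
        genotypes=geno,
        samples=samples,
        populations={s: s.rsplit("_", 1)[0] for s in samples},
    )


def random_binary_newick(rng, labels):
    """Random bifurcating tree over ``labels`` by sequential random joining."""
    nodes = list(labels)
    while len(nodes) > 1:
        i = rng.integers(0, len(nodes))
        a = nodes.pop(i)
        j = rng.integers(0, len(nodes))
        b = nodes.pop(j)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
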