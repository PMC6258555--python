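import numpy as np
import pandas as pd
import pytest

from divflow.datatypes import GenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotype_table(genotypes, populations=None, ecotypes=None,
                        loci=None, positions=None):
    """Assemble a GenotypeTable from plain arrays with default metadata."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_sites = genotypes.shape
    if populations is None:
        populations = ["pop1"] * (n_ind // 2) + \
            ["pop2"] * (n_ind - n_ind // 2)
    if ecotypes is None:
        ecotypes = ["S" if p == "pop1" else "L" for p in populations]
    habitat = [-1 if e == "S" else 1 for e in ecotypes]
    samples = pd.DataFrame({
        "id": [f"ind{i:03d}" for i in range(n_ind)],
        "population": populations, "ecotype": ecotypes,
        "habitat": habitat,
    })
    if loci is None:
        loci = [f"L{s // 4}" for s in range(n_sites)]
    if positions is None:
        positions = [(s % 4) * 50 for s in range(n_sites)]
    sites = pd.DataFrame({"locus": loci, "pos": positions,
                          "ref": "A", "alt": "G"})
    return GenotypeTable(genotypes, samples, sites)


@pytest.fixture
def toy_table():
    """Ten diploids x eight SNPs over two loci, no missing data."""
    rng = np.random.default_rng(7)
    g = rng.integers(0, 3, size=(10, 8))
    return make_genotype_table(g)
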