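import pytest

from kirpop import (
    DEFAULT_PANEL,
    GenotypeProfile,
    default_reference_haplotypes,
)

A_GENOTYPE = frozenset(
    {"3DL3", "2DL3", "2DP1", "2DL1", "3DP1", "2DL4", "3DL1", "2DS4", "3DL2"}
)


def make_profile(iid, genes, ds4_zygosity=None):
    genes = frozenset(genes)
    present = {g: (g in genes) for g in DEFAULT_PANEL.genes}
    return GenotypeProfile(iid, present, ds4_zygosity)


@pytest.fixture(scope="session")
def refs():
    return default_reference_haplotypes()


@pytest.fixture(scope="session")
def ref_genes(refs):
    return {h.name: h.genes for h in refs}


@pytest.fixture
def aa_profile():
    return make_profile("AA1", A_GENOTYPE)
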