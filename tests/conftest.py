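"""Shared fixtures: small synthetic datasets generated at test time."""

import pytest

from mtbarcode.profiles import PCG_GENES
from mtbarcode.simulate import SubstitutionModel, SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Gap-positive dataset: 8 genera x 2 species x 2 sequences, 12 genes."""
    cfg = SyntheticConfig(
        n_genera=8,
        species_per_genus=2,
        seqs_per_species=2,
        gene_lengths={g: 1200 for g in PCG_GENES},
        seed=101,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_locus_dataset():
    """Single 3 kb locus over 10 ingroup + 2 outgroup sequences."""
    cfg = SyntheticConfig(
        n_genera=5,
        species_per_genus=1,
        seqs_per_species=2,
        gene_lengths={"locus": 3000},
        model=SubstitutionModel(alpha=None, prop_invariable=0.0),
        seed=7,
    )
    return simulate_dataset(cfg)
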