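import numpy as np
import pytest

from ltrdomains import simulate


@pytest.fixture(scope="session")
def library():
    return simulate.generate_profile_library(seed=0)


@pytest.fixture(scope="session")
def rt_profiles(library):
    return library.family_profiles("RT")


@pytest.fixture(scope="session")
def single_copy_genome(library):
    """One zero-divergence Gypsy-like element in a 20 kb contig."""
    spec = simulate.gypsy_odd_spec(copy_number=1, divergence=0.0)
    gspec = simulate.GenomeSimSpec(
        species_id="sp", genome_len=20000, elements=(spec,), seed=11
    )
    records, truth = simulate.generate_genome(gspec, library)
    return records, truth


@pytest.fixture(scope="session")
def family_genome(library):
    """Six copies of one Gypsy-like family at 3% divergence."""
    spec = simulate.gypsy_odd_spec(copy_number=6, divergence=0.03)
    gspec = simulate.GenomeSimSpec(
        species_id="sp", genome_len=110000, elements=(spec,), seed=5
    )
    records, truth = simulate.generate_genome(gspec, library)
    return records, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
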