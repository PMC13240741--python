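from __future__ import annotations

import pytest

from alleleauto.filtering import FilterConfig, identify_alleles
from alleleauto.simulate import SimConfig, simulate_diploid


@pytest.fixture(scope="session")
def default_sim():
    """The reference simulation: 2 chromosome pairs x 1000 genes,
    allelic Ks ~ N(0.03, 0.01^2), 100 paralog decoys with Ks in
    [0.3, 1.0], one 50-gene inversion, seed 1."""
    return simulate_diploid(SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def default_identify(default_sim):
    """Sigma-rule identification run on the reference simulation."""
    return identify_alleles(
        default_sim.genes_a,
        default_sim.genes_b,
        default_sim.chromosome_map,
        config=FilterConfig(method="sigma"),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A fast 1 x 300 gene simulation with 20 decoys for unit tests."""
    return simulate_diploid(SimConfig(
        n_chrom_pairs=1, genes_per_chrom=300, n_paralogs=20,
        inversion_length=30, rng_seed=11,
    ))
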