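import numpy as np
import pytest

from varldkit import GenotypePanel, SimulationConfig, Variant, ar1, simulate_pair


def make_variants(positions, chrom="12", alleles=("A", "G"), prefix="rs"):
    return [Variant(id=f"{prefix}{i + 1}", chrom=chrom, pos=int(p),
                    allele_a=alleles[0], allele_b=alleles[1])
            for i, p in enumerate(positions)]


def panel_from_dosages(dosages, positions=None, population="pop",
                       chrom="12", variants=None):
    """Build an unphased panel from a dosage matrix (helper for fixtures)."""
    dosages = np.asarray(dosages, dtype=float)
    if variants is None:
        if positions is None:
            positions = 1000 * (np.arange(dosages.shape[1]) + 1)
        variants = make_variants(positions, chrom=chrom)
    return GenotypePanel(population=population, variants=variants,
                         dosages=dosages, phased=False)


def panel_from_haplotypes(haps, positions=None, population="pop", chrom="12"):
    """Build a phased panel from a 2n x m binary haplotype matrix."""
    haps = np.asarray(haps, dtype=float)
    if positions is None:
        positions = 1000 * (np.arange(haps.shape[1]) + 1)
    return GenotypePanel(
        population=population,
        variants=make_variants(positions, chrom=chrom),
        dosages=haps[0::2] + haps[1::2],
        haplotypes=haps,
        phased=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def null_pair():
    """Two panels drawn from one AR(1) law (null for the permutation test)."""
    cfg = SimulationConfig(m=15, n1=60, n2=60, structure=ar1(0.8), seed=11)
    return simulate_pair(cfg)


@pytest.fixture
def divergent_pair():
    """Strongly LD-divergent panel pair (alternative for power checks)."""
    cfg = SimulationConfig(m=20, n1=80, n2=80, structure=ar1(0.9),
                           divergence=("ar1_contrast", 0.9, 0.2), seed=12)
    return simulate_pair(cfg)
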