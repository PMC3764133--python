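"""Synthetic two-population haplotype panels with controlled LD structure.

Haplotypes are drawn through a Gaussian copula: a latent multivariate
normal vector with a target correlation matrix is thresholded per SNP at
the normal quantile of that SNP's allele frequency, producing correlated
binary haplotypes with exactly calibrated marginals.  Consecutive
haplotypes are paired into diploid individuals.  The copula attenuates
correlation on the binary scale (|r| of the 0/1 variables is below the
latent rho), so tests and analyses always work with empirical LD matrices,
never with the latent targets.

Divergence between the two panels is introduced either by giving each
panel a different AR(1) decay (``ar1_contrast``) or by permuting a
fraction of SNP labels inside the second panel's target matrix
(``block_permute``), which destroys positional LD while preserving the
spectrum's scale.  ``divergence="none"`` yields two independent samples
from one law — the null of the permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_panels import GenotypePanel, Variant

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-6


@dataclass
class SimulationConfig:
    """Study-condition knobs for the two-population generator.

    Defaults mirror a desk-scale version of a regional two-panel LD
    comparison: ~200 kb of SNPs at 1.6 kb spacing on chromosome 12
    starting at 38,705,000 bp, diploid sample sizes in the 80-200 range,
    and a moderate AR(1) LD backbone.
    """

    m: int = 120
    n1: int = 100
    n2: int = 100
    freq_range: tuple[float, float] = (0.05, 0.5)
    structure: tuple = ("ar1", 0.8)
    divergence: tuple = ("none",)
    chrom: str = "12"
    start_bp: int = 38_705_000
    spacing_bp: int = 1_600
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        if not (0 < self.freq_range[0] <= self.freq_range[1] <= 0.5):
            raise ValueError("freq_range must satisfy 0 < lo <= hi <= 0.5")
        if self.m < 2 or self.n1 < 2 or self.n2 < 2:
            raise ValueError("m, n1, n2 must all be >= 2")


def ar1(rho: float) -> tuple:
    """AR(1) correlation target: corr(i, j) = rho^|i-j|."""
    if not -1 < rho < 1:
        raise ValueError("ar1 rho must be in (-1, 1)")
    return ("ar1", rho)


def block_structure(sizes: list[int], within_r: float,
                    between_r: float = 0.0) -> tuple:
    """Block-diagonal correlation target (uniform within, uniform between)."""
    return ("block", tuple(sizes), within_r, between_r)


def build_correlation(structure: tuple | np.ndarray, m: int) -> np.ndarray:
    """Materialise a target correlation matrix; repair to positive definite
    by clipping eigenvalues at 1e-6 and re-normalising the diagonal."""
    if isinstance(structure, np.ndarray):
        target = np.array(structure, dtype=float)
        if target.shape != (m, m):
            raise ValueError(f"custom matrix must be {m} x {m}")
    elif structure[0] == "ar1":
        rho = structure[1]
        idx = np.arange(m)
        target = rho ** np.abs(idx[:, None] - idx[None, :])
    elif structure[0] == "block":
        sizes, within_r, between_r = structure[1], structure[2], structure[3]
        if sum(sizes) != m:
            raise ValueError(f"block sizes sum to {sum(sizes)}, expected {m}")
        target = np.full((m, m), between_r, dtype=float)
        off = 0
        for s in sizes:
            target[off:off + s, off:off + s] = within_r
            off += s
        np.fill_diagonal(target, 1.0)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    if not np.allclose(target, target.T):
        raise ValueError("correlation target must be symmetric")
    lam, vec = np.linalg.eigh(target)
    if lam.min() < _EIG_FLOOR:
        logger.info("correlation target repaired: clipped %d eigenvalues "
                    "below %g", int(np.sum(lam < _EIG_FLOOR)), _EIG_FLOOR)
        lam = np.clip(lam, _EIG_FLOOR, None)
        target = (vec * lam) @ vec.T
        d = np.sqrt(np.diag(target))
        target = target / np.outer(d, d)
        np.fill_diagonal(target, 1.0)
    return target


def _population_target(config: SimulationConfig, population_index: int,
                       rng_structure: np.random.Generator) -> np.ndarray:
    """Resolve the correlation target for one population under the
    configured divergence."""
    kind = config.divergence[0]
    if kind == "none":
        return build_correlation(config.structure, config.m)
    if kind == "ar1_contrast":
        rho = config.divergence[1 + population_index]
        return build_correlation(ar1(rho), config.m)
    if kind == "block_permute":
        base = build_correlation(config.structure, config.m)
        if population_index == 0:
            return base
        fraction = config.divergence[1]
        k = int(np.ceil(fraction * config.m))
        idx = rng_structure.choice(config.m, size=k, replace=False)
        perm = np.arange(config.m)
        perm[idx] = idx[rng_structure.permutation(k)]
        return base[np.ix_(perm, perm)]
    raise ValueError(f"unknown divergence {config.divergence!r}")


def _variants(config: SimulationConfig) -> list[Variant]:
    return [Variant(id=f"snp{i + 1:04d}", chrom=config.chrom,
                    pos=config.start_bp + i * config.spacing_bp,
                    allele_a="A", allele_b="G")
            for i in range(config.m)]


def simulate_haplotypes(config: SimulationConfig,
                        population_index: int = 0) -> GenotypePanel:
    """Draw one phased diploid panel under the config.

    Allele frequencies and any structural randomness (e.g. the
    block-permute label shuffle) depend only on ``config.seed`` so both
    populations of a pair share them; the haplotype draw itself uses a
    stream keyed by (seed, population_index).
    """
    if population_index not in (0, 1):
        raise ValueError("population_index must be 0 or 1")
    shared = np.random.default_rng(np.random.SeedSequence(config.seed))
    freqs = shared.uniform(config.freq_range[0], config.freq_range[1],
                           size=config.m)
    target = _population_target(config, population_index, shared)
    chol = np.linalg.cholesky(target)
    n = (config.n1, config.n2)[population_index]
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(population_index + 1,)))
    z = rng.standard_normal((2 * n, config.m)) @ chol.T
    hap = (z <= stats.norm.ppf(freqs)).astype(float)
    dosages = hap[0::2] + hap[1::2]
    if config.missing_rate > 0:
        mask = rng.random((n, config.m)) < config.missing_rate
        # keep at least one observation per SNP
        full_cols = mask.all(axis=0)
        mask[0, full_cols] = False
        dosages = dosages.copy()
        dosages[mask] = np.nan
        hap = hap.copy()
        hap[np.repeat(mask, 2, axis=0)] = np.nan
    return GenotypePanel(population=f"pop{population_index + 1}",
                         variants=_variants(config), dosages=dosages,
                         haplotypes=hap, phased=True)


def simulate_pair(config: SimulationConfig) -> tuple[GenotypePanel, GenotypePanel]:
    """Two panels sharing allele frequencies, with LD structure equal
    (``divergence=("none",)``) or divergent per the config."""
    return (simulate_haplotypes(config, 0), simulate_haplotypes(config, 1))


def write_fixture(panel: GenotypePanel, path: str, format: str = "vcf") -> None:
    """Persist a panel in a reader-round-trippable text format."""
    from . import io_panels

    if format == "vcf":
        io_panels.write_vcf(panel, path)
    elif format == "hapmap_table":
        io_panels.write_hapmap_table(panel, path)
    else:
        raise ValueError(f"unknown fixture format {format!r}")
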