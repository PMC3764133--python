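"""Pairwise linkage-disequilibrium statistics, regional LD matrices and
focal-SNP LD profiles.

Two computation modes are supported and must be used consistently across
populations in any comparison:

``haplotype_counted``
    direct haplotype counting on phased data; yields D, D', signed r, r2.
``genotype_corr``
    composite signed correlation of allele-b dosages (the statistic the
    varLD method consumes for unphased data); D and D' are not defined.
``haplotype_em``
    two-locus haplotype frequencies estimated from unphased genotypes by
    EM under Hardy-Weinberg equilibrium, then the haplotype formulas.

Missing data are handled by pairwise-complete deletion; a pair with fewer
than ``MIN_COMPLETE`` complete observations, or monomorphic at either
locus, has undefined LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedLDError
from .io_panels import GenotypePanel

logger = logging.getLogger(__name__)

#: Minimum pairwise-complete observations for a defined LD estimate.
MIN_COMPLETE = 4

MODES = ("genotype_corr", "haplotype_em", "haplotype_counted")


@dataclass(frozen=True)
class PairLD:
    """Two-locus LD summary: D, D' (haplotype modes only), signed r, r2."""

    r: float
    r2: float
    d: float | None = None
    d_prime: float | None = None


@dataclass
class LDMatrix:
    """Signed-correlation LD matrix over an ordered SNP list.

    ``r_signed`` is symmetric with unit diagonal; the r2 view is its
    elementwise square.
    """

    variant_ids: list[str]
    r_signed: np.ndarray
    method: str
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r_signed = np.asarray(self.r_signed, dtype=float)
        m = len(self.variant_ids)
        if self.r_signed.shape != (m, m):
            raise ValueError("r_signed must be m x m")

    @property
    def m(self) -> int:
        return len(self.variant_ids)

    @property
    def r2(self) -> np.ndarray:
        return self.r_signed ** 2

    def to_long_frame(self):
        """Long-format table (snp1, snp2, r, r2) over upper-triangle pairs."""
        import pandas as pd

        ids = self.variant_ids
        iu, ju = np.triu_indices(self.m, k=1)
        return pd.DataFrame({
            "snp1": [ids[i] for i in iu],
            "snp2": [ids[j] for j in ju],
            "r": self.r_signed[iu, ju],
            "r2": self.r2[iu, ju],
        })

    def write_square(self, path: str) -> None:
        """Square tab-delimited export with SNP ids as header row/column."""
        with open(path, "w") as fh:
            fh.write("snp\t" + "\t".join(self.variant_ids) + "\n")
            for i, vid in enumerate(self.variant_ids):
                fh.write(vid + "\t"
                         + "\t".join(f"{x:.6g}" for x in self.r_signed[i])
                         + "\n")


@dataclass
class LDProfile:
    """r2 of every regional SNP against one focal SNP, in position order."""

    focal_id: str
    variant_ids: list[str]
    positions: np.ndarray
    r2_values: np.ndarray
    population: str = ""


def _drop_joint_missing(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = ~np.isnan(a) & ~np.isnan(b)
    return a[ok], b[ok]


def pair_ld_haplotypes(hap_a: np.ndarray, hap_b: np.ndarray) -> PairLD:
    """LD between two loci from aligned binary haplotype vectors.

    With p_AB the frequency of the (1,1) haplotype and p_A, p_B the allele-1
    frequencies: D = p_AB - p_A p_B, r = D / sqrt(p_A q_A p_B q_B), and
    D' = |D| / D_max with the sign-dependent bound on D.
    """
    a, b = _drop_joint_missing(np.asarray(hap_a, float), np.asarray(hap_b, float))
    if a.size < MIN_COMPLETE:
        raise UndefinedLDError(
            f"only {a.size} complete haplotypes (< {MIN_COMPLETE})")
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise UndefinedLDError("monomorphic locus among complete haplotypes")
    p_ab = np.mean(a * b)
    return _pair_ld_from_freqs(p_ab, p_a, p_b)


def _pair_ld_from_freqs(p_ab: float, p_a: float, p_b: float) -> PairLD:
    d = p_ab - p_a * p_b
    denom = np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    r = d / denom
    if d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    d_prime = 0.0 if d_max == 0 else min(abs(d) / d_max, 1.0)
    return PairLD(r=float(r), r2=float(r * r), d=float(d), d_prime=float(d_prime))


def pair_ld_genotypes(g1: np.ndarray, g2: np.ndarray,
                      mode: str = "genotype_corr") -> PairLD:
    """LD between two loci from dosage vectors.

    ``genotype_corr`` returns the Pearson correlation of dosages (D and D'
    unset); ``haplotype_em`` estimates the four two-locus haplotype
    frequencies by EM and applies the haplotype formulas.
    """
    g1, g2 = _drop_joint_missing(np.asarray(g1, float), np.asarray(g2, float))
    if g1.size < MIN_COMPLETE:
        raise UndefinedLDError(
            f"only {g1.size} pairwise-complete genotypes (< {MIN_COMPLETE})")
    if np.var(g1) == 0 or np.var(g2) == 0:
        raise UndefinedLDError("zero dosage variance at a locus")
    if mode == "genotype_corr":
        r = float(np.corrcoef(g1, g2)[0, 1])
        return PairLD(r=r, r2=r * r)
    if mode == "haplotype_em":
        from .haplotypes import em_two_locus

        p_ab, p_a, p_b = em_two_locus(g1, g2)
        if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
            raise UndefinedLDError("monomorphic locus")
        return _pair_ld_from_freqs(p_ab, p_a, p_b)
    raise ValueError(f"unknown mode {mode!r}")


def _data_matrix(panel: GenotypePanel, mode: str) -> tuple[np.ndarray, str]:
    """Resolve the working matrix for a mode; 'auto' picks haplotype
    counting when phased, genotype correlation otherwise."""
    if mode == "auto":
        mode = "haplotype_counted" if panel.phased else "genotype_corr"
    if mode == "haplotype_counted":
        if not panel.phased:
            raise ValueError("haplotype_counted mode requires a phased panel")
        return panel.haplotypes, mode
    if mode in ("genotype_corr", "haplotype_em"):
        return panel.dosages, mode
    raise ValueError(f"unknown LD mode {mode!r}")


def _corr_complete(x: np.ndarray) -> np.ndarray:
    """Correlation matrix of columns with no missing entries (fast path)."""
    z = x - x.mean(axis=0)
    sd = z.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = z / sd_safe
    r = (z.T @ z) / x.shape[0]
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    return r


def _corr_pairwise(x: np.ndarray) -> np.ndarray:
    """Pairwise-complete correlation matrix; undefined entries are NaN."""
    m = x.shape[1]
    r = np.full((m, m), np.nan)
    for i in range(m):
        r[i, i] = 1.0
        for j in range(i + 1, m):
            a, b = _drop_joint_missing(x[:, i], x[:, j])
            if a.size < MIN_COMPLETE or np.var(a) == 0 or np.var(b) == 0:
                continue
            r[i, j] = r[j, i] = np.corrcoef(a, b)[0, 1]
    return r


def ld_matrix(panel: GenotypePanel, mode: str = "auto",
              strict: bool = False) -> LDMatrix:
    """Signed-r LD matrix over all SNP pairs of a panel.

    Pairs with undefined LD are set to r=0 (logged) so downstream
    eigen-analysis never sees NaN; with ``strict=True`` they raise instead.
    """
    if panel.n_variants < 2:
        raise ValueError("LD matrix requires >= 2 variants")
    x, resolved = _data_matrix(panel, mode)
    if resolved == "haplotype_em":
        m = panel.n_variants
        r = np.full((m, m), np.nan)
        np.fill_diagonal(r, 1.0)
        for i in range(m):
            for j in range(i + 1, m):
                try:
                    r[i, j] = r[j, i] = pair_ld_genotypes(
                        x[:, i], x[:, j], mode="haplotype_em").r
                except UndefinedLDError:
                    pass
    elif np.isnan(x).any():
        r = _corr_pairwise(x)
    else:
        r = _corr_complete(x)
    und = np.isnan(r)
    np.fill_diagonal(und, False)
    if und.any():
        if strict:
            raise UndefinedLDError(
                f"{und.sum() // 2} SNP pairs with undefined LD")
        logger.info("ld_matrix(%s): %d undefined pairs set to r=0",
                    panel.population, und.sum() // 2)
        r[und] = 0.0
    np.fill_diagonal(r, 1.0)
    if np.isnan(r).any():
        raise UndefinedLDError("undefined LD on the diagonal (monomorphic SNP)")
    return LDMatrix(variant_ids=panel.variant_ids, r_signed=r,
                    method=resolved, positions=panel.positions)


def ld_profile(panel: GenotypePanel, focal_id: str,
               mode: str = "auto") -> LDProfile:
    """r2 of the focal SNP against every other SNP, in position order."""
    k = panel.variant_index(focal_id)
    x, resolved = _data_matrix(panel, mode)
    focal = x[:, k]
    ok = ~np.isnan(focal)
    if np.var(focal[ok]) == 0:
        raise UndefinedLDError(f"focal SNP {focal_id} is monomorphic")
    r2 = np.zeros(panel.n_variants)
    for j in range(panel.n_variants):
        if j == k:
            r2[j] = 1.0
            continue
        try:
            if resolved == "haplotype_counted":
                r2[j] = pair_ld_haplotypes(focal, x[:, j]).r2
            else:
                r2[j] = pair_ld_genotypes(focal, x[:, j], mode=resolved).r2
        except UndefinedLDError:
            r2[j] = 0.0
    return LDProfile(focal_id=focal_id, variant_ids=panel.variant_ids,
                     positions=panel.positions, r2_values=r2,
                     population=panel.population)
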