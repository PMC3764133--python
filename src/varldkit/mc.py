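"""Monte Carlo permutation significance for the varLD score.

The null hypothesis is that the two population samples are drawn from one
population with a common LD structure.  It is tested by pooling the two
samples and repeatedly re-partitioning whole individuals (both haplotypes
move together) into groups of the original sizes, recomputing the varLD
score for each partition.  The empirical p-value uses the add-one
estimator

    p = (1 + #{replicate >= observed}) / (1 + B),

which is strictly positive and attains its floor 1/(B+1) — 0.0001 at
B = 10,000 — when the observed score exceeds every replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import PanelError
from .io_panels import GenotypePanel, RegionSpec, extract_region, harmonize_panels
from .ld import _data_matrix, ld_matrix
from .varld import varld_raw_score, varld_score_from_matrices

logger = logging.getLogger(__name__)


@dataclass
class MCResult:
    """One pairwise varLD permutation test."""

    observed: float
    replicates: np.ndarray
    b: int
    p_value: float
    seed: int | None
    n1: int
    n2: int
    m: int


@dataclass
class ComparisonTable:
    """Multi-pair varLD comparison with family-wise Bonferroni control."""

    rows: pd.DataFrame
    alpha_family: float
    alpha_per_test: float
    n_comparisons: int

    def to_tsv(self, path: str) -> None:
        """Tab-delimited export; scores at 6 s.f., p-values at 4 d.p."""
        df = self.rows.copy()
        df["score"] = df["score"].map(lambda x: f"{x:.6g}")
        df["p_value"] = df["p_value"].map(lambda x: f"{x:.4f}")
        df.to_csv(path, sep="\t", index=False)


def merge_panels(p1: GenotypePanel, p2: GenotypePanel) -> GenotypePanel:
    """Row-concatenate two harmonized panels into one pooled panel."""
    k1 = [(v.chrom, v.pos, v.allele_a, v.allele_b) for v in p1.variants]
    k2 = [(v.chrom, v.pos, v.allele_a, v.allele_b) for v in p2.variants]
    if k1 != k2:
        raise PanelError("cannot merge panels with different variant lists; "
                         "harmonize first")
    phased = p1.phased and p2.phased
    hap = None
    if phased:
        hap = np.vstack([p1.haplotypes, p2.haplotypes])
    return GenotypePanel(
        population=f"{p1.population}+{p2.population}",
        variants=list(p1.variants),
        dosages=np.vstack([p1.dosages, p2.dosages]),
        haplotypes=hap,
        phased=phased,
    )


def resample_split(merged: GenotypePanel, n1: int, n2: int,
                   rng: np.random.Generator) -> tuple[GenotypePanel, GenotypePanel]:
    """Uniformly random partition of the merged individuals into n1 + n2.

    Sampling is without replacement and moves whole individuals, i.e. it
    permutes population labels.
    """
    if n1 + n2 != merged.n_samples:
        raise ValueError(
            f"n1 + n2 = {n1 + n2} != merged sample count {merged.n_samples}")
    perm = rng.permutation(merged.n_samples)
    return (merged.subset_samples(perm[:n1], population="resample_1"),
            merged.subset_samples(perm[n1:], population="resample_2"))


def _corr_fast(x: np.ndarray) -> np.ndarray:
    """Column correlation with zero-variance columns mapped to r=0 off the
    diagonal (matching non-strict ld_matrix)."""
    z = x - x.mean(axis=0)
    sd = z.std(axis=0)
    dead = sd == 0
    z = z / np.where(dead, 1.0, sd)
    r = (z.T @ z) / x.shape[0]
    if dead.any():
        r[dead, :] = 0.0
        r[:, dead] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def mc_pvalue(p1: GenotypePanel, p2: GenotypePanel, b: int,
              mode: str = "auto", rng_seed: int | None = 0) -> MCResult:
    """Permutation p-value for the regional varLD score of two panels.

    Panels must be harmonized (identical variant lists).  ``b`` replicate
    scores are drawn by label permutation of the pooled sample; the
    reported p is (1 + #{replicate >= observed}) / (1 + b).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if p1.variant_ids != p2.variant_ids:
        raise PanelError("panels must be harmonized before mc_pvalue")
    observed = varld_raw_score(ld_matrix(p1, mode=mode),
                               ld_matrix(p2, mode=mode)).score
    merged = merge_panels(p1, p2)
    n1, n2 = p1.n_samples, p2.n_samples
    rng = np.random.default_rng(rng_seed)

    x, resolved = _data_matrix(merged, mode)
    replicates = np.empty(b)
    fast = resolved in ("genotype_corr", "haplotype_counted") \
        and not np.isnan(x).any()
    if fast:
        per_individual = resolved == "genotype_corr"
        for t in range(b):
            perm = rng.permutation(merged.n_samples)
            if per_individual:
                x1, x2 = x[perm[:n1]], x[perm[n1:]]
            else:
                h1 = np.empty(2 * n1, dtype=int)
                h1[0::2], h1[1::2] = 2 * perm[:n1], 2 * perm[:n1] + 1
                h2 = np.empty(2 * n2, dtype=int)
                h2[0::2], h2[1::2] = 2 * perm[n1:], 2 * perm[n1:] + 1
                x1, x2 = x[h1], x[h2]
            replicates[t] = varld_score_from_matrices(_corr_fast(x1),
                                                      _corr_fast(x2))
    else:
        for t in range(b):
            q1, q2 = resample_split(merged, n1, n2, rng)
            replicates[t] = varld_raw_score(ld_matrix(q1, mode=mode),
                                            ld_matrix(q2, mode=mode)).score
    k = int(np.sum(replicates >= observed))
    p = (1 + k) / (1 + b)
    return MCResult(observed=observed, replicates=replicates, b=b, p_value=p,
                    seed=rng_seed if isinstance(rng_seed, int) else None,
                    n1=n1, n2=n2, m=p1.n_variants)


def bonferroni_adjust(p_values: np.ndarray,
                      alpha_family: float = 0.05) -> tuple[float, np.ndarray]:
    """Bonferroni per-test threshold and strict significance flags.

    alpha_per_test = alpha_family / n_comparisons; a test is significant
    iff p < alpha_per_test (strict, so p exactly at the threshold is not).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if not 0 < alpha_family < 1:
        raise ValueError("alpha_family must be in (0, 1)")
    alpha_per_test = alpha_family / p.size
    return alpha_per_test, p < alpha_per_test


def pool_panels(members: list[GenotypePanel], name: str,
                maf_min: float = 0.01) -> GenotypePanel:
    """Concatenate several panels after multi-way harmonization to their
    common SNP set (alleles aligned to the first member)."""
    if len(members) == 1:
        out = members[0]
        return GenotypePanel(population=name, variants=list(out.variants),
                             dosages=out.dosages.copy(),
                             haplotypes=None if out.haplotypes is None
                             else out.haplotypes.copy(),
                             phased=out.phased)
    ref = members[0]
    aligned: list[GenotypePanel] = []
    for pk in members[1:]:
        ref, pk_aligned = harmonize_panels(ref, pk, maf_min=maf_min)
        aligned.append(pk_aligned)
    final_pos = [(v.chrom, v.pos) for v in ref.variants]
    parts = [ref]
    for pk in aligned:
        lut = {(v.chrom, v.pos): j for j, v in enumerate(pk.variants)}
        parts.append(pk.subset_variants([lut[key] for key in final_pos]))
    phased = all(p.phased for p in parts)
    return GenotypePanel(
        population=name,
        variants=list(ref.variants),
        dosages=np.vstack([p.dosages for p in parts]),
        haplotypes=np.vstack([p.haplotypes for p in parts]) if phased else None,
        phased=phased,
    )


def pairwise_comparison_table(
    panels: dict[str, GenotypePanel] | list[GenotypePanel],
    pairs: list[tuple[str, str]],
    region: RegionSpec | None = None,
    b: int = 10_000,
    alpha_family: float = 0.05,
    mode: str = "auto",
    rng_seed: int = 0,
    pools: dict[str, list[str]] | None = None,
    maf_min: float = 0.01,
) -> ComparisonTable:
    """One varLD permutation test per requested population pair.

    ``pools`` declares pooled panels (e.g. ``{"Asian": ["CHB", "JPT", ...]}``)
    built by multi-way harmonization and concatenation.  Bonferroni
    correction is applied across exactly the requested pairs.  Per-pair RNG
    streams are spawned from ``rng_seed`` so each row is independently
    reproducible.
    """
    if not pairs:
        raise ValueError("no pairs requested")
    if isinstance(panels, list):
        panels = {p.population: p for p in panels}
    panels = dict(panels)
    for pool_name, members in (pools or {}).items():
        missing = [x for x in members if x not in panels]
        if missing:
            raise KeyError(f"pool {pool_name!r} references unknown panels "
                           f"{missing}")
        panels[pool_name] = pool_panels([panels[x] for x in members],
                                        pool_name, maf_min=maf_min)
    for a, c in pairs:
        for label in (a, c):
            if label not in panels:
                raise KeyError(f"unknown population label {label!r}")

    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(pairs))
    records = []
    for idx, (a, c) in enumerate(pairs):
        pa, pc = panels[a], panels[c]
        if region is not None:
            pa = extract_region(pa, region)
            pc = extract_region(pc, region)
        ha, hc = harmonize_panels(pa, pc, maf_min=maf_min)
        res = mc_pvalue(ha, hc, b=b, mode=mode, rng_seed=children[idx])
        records.append({
            "pop1": a, "pop2": c,
            "region": _region_label(region),
            "m_snps": res.m,
            "score": res.observed,
            "p_value": res.p_value,
        })
    df = pd.DataFrame.from_records(records)
    alpha_per_test, flags = bonferroni_adjust(df["p_value"].to_numpy(),
                                              alpha_family)
    df["significant"] = flags
    return ComparisonTable(rows=df, alpha_family=alpha_family,
                           alpha_per_test=alpha_per_test,
                           n_comparisons=len(pairs))


def _region_label(region: RegionSpec | None) -> str:
    if region is None:
        return "all"
    return (f"{region.chrom}:{region.padded_start / 1e6:.3f}"
            f"-{region.padded_end / 1e6:.3f}Mb")
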