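"""Haplotype-frequency estimation, haplotype blocks and tag SNPs.

Multilocus haplotype frequencies are estimated from unphased genotypes by
the classical EM algorithm (expectation over phase resolutions consistent
with each multilocus genotype, maximisation by re-normalising expected
haplotype counts), which assumes Hardy-Weinberg equilibrium.  Phased
panels are handled by direct counting.

Blocks follow the D'-confidence-interval construction: a SNP pair is in
"strong LD" when the profile-likelihood CI of D' has a high lower bound
and an upper bound near 1, and a contiguous span of SNPs is a block when
at least 95% of its informative pairs are strong.  A four-gamete
alternative (a span is a block when no internal pair shows all four
gametes at frequency >= 1%) is also provided.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import UndefinedLDError
from .io_panels import GenotypePanel

logger = logging.getLogger(__name__)

#: hard cap on phase resolutions enumerated per sample in the EM
_MAX_RESOLUTIONS = 1 << 16


@dataclass
class HaplotypeFreqTable:
    """Estimated multilocus haplotype frequencies over an ordered SNP set."""

    snp_ids: list[str]
    haplotypes: list[str]
    frequencies: np.ndarray
    n_chromosomes: int
    log_likelihood: float

    def common(self, min_freq: float = 0.05) -> "HaplotypeFreqTable":
        """Restrict to haplotypes at or above ``min_freq`` (report view;
        frequencies are not renormalised)."""
        keep = self.frequencies >= min_freq
        return HaplotypeFreqTable(
            snp_ids=self.snp_ids,
            haplotypes=[h for h, k in zip(self.haplotypes, keep) if k],
            frequencies=self.frequencies[keep],
            n_chromosomes=self.n_chromosomes,
            log_likelihood=self.log_likelihood,
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.haplotypes, self.frequencies.tolist()))

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("haplotype\tfrequency\n")
            for h, f in zip(self.haplotypes, self.frequencies):
                fh.write(f"{h}\t{f:.6g}\n")


@dataclass
class Block:
    """A contiguous haplotype block; bounds are member SNP min/max positions."""

    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class TagSet:
    """Greedy tag-SNP cover: every non-tag SNP has r2 >= threshold with a tag."""

    tags: list[str]
    r2_threshold: float
    coverage_map: dict[str, tuple[str, float]]


# ---------------------------------------------------------------------------
# EM haplotype-frequency estimation
# ---------------------------------------------------------------------------

def _resolutions(genotype: tuple[float, ...]) -> list[tuple[int, int]]:
    """Ordered haplotype pairs (as bit-packed ints, MSB = first SNP)
    consistent with one multilocus genotype; NaN entries unconstrained."""
    k = len(genotype)
    free1: list[int] = []   # positions where h1 is free
    free2: list[int] = []   # positions where h2 is free given h1
    base1 = 0
    het = []
    for pos, g in enumerate(genotype):
        bit = k - 1 - pos
        if np.isnan(g):
            free1.append(bit)
            free2.append(bit)
        elif g == 1:
            free1.append(bit)
            het.append(bit)
        elif g == 2:
            base1 |= 1 << bit
    n_res = (1 << len(free1)) * (1 << len(free2))
    if n_res > _MAX_RESOLUTIONS:
        raise OverflowError("too many phase resolutions")
    out = []
    for bits1 in itertools.product((0, 1), repeat=len(free1)):
        h1 = base1
        for bit, v in zip(free1, bits1):
            h1 |= v << bit
        # h2: hom positions same as h1 base; het positions complementary
        h2_fixed = base1
        for bit in het:
            h2_fixed |= (0 if (h1 >> bit) & 1 else 1) << bit
        for bits2 in itertools.product((0, 1), repeat=len(free2)):
            h2 = h2_fixed
            for bit, v in zip(free2, bits2):
                h2 = (h2 & ~(1 << bit)) | (v << bit)
            out.append((h1, h2))
    return out


def em_haplotype_freqs(panel: GenotypePanel, snp_ids: list[str],
                       max_iter: int = 1000,
                       tol: float = 1e-7) -> HaplotypeFreqTable:
    """EM haplotype frequencies for 2-12 SNPs of a panel.

    Phased panels without missing data at the chosen SNPs are counted
    directly (the EM has nothing to resolve); otherwise the EM is
    initialised at linkage-equilibrium product frequencies and iterated
    until the log-likelihood change falls below ``tol``.
    """
    k = len(snp_ids)
    if not 2 <= k <= 12:
        raise ValueError(f"number of SNPs must be in [2, 12], got {k}")
    cols = [panel.variant_index(s) for s in snp_ids]
    n_hap = 1 << k

    if panel.phased:
        h = panel.haplotypes[:, cols]
        ok = ~np.isnan(h).any(axis=1)
        if ok.all():
            codes = (h[ok].astype(int)
                     @ (1 << np.arange(k - 1, -1, -1))).astype(int)
            counts = np.bincount(codes, minlength=n_hap).astype(float)
            freqs = counts / counts.sum()
            with np.errstate(divide="ignore"):
                ll = float(np.sum(counts[counts > 0]
                                  * np.log(freqs[counts > 0])))
            return _freq_table(snp_ids, freqs, int(counts.sum()), ll, k)

    g = panel.dosages[:, cols]
    keep = ~np.isnan(g).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("em_haplotype_freqs: dropped %d all-missing samples",
                    n_dropped)
    g = g[keep]
    if g.shape[0] == 0:
        raise ValueError("no samples with observed genotypes")

    # group identical genotype rows
    groups: dict[tuple, int] = {}
    for row in map(tuple, g):
        groups[row] = groups.get(row, 0) + 1
    res_list: list[tuple[np.ndarray, np.ndarray, int]] = []
    n_used = 0
    for row, cnt in groups.items():
        try:
            pairs = _resolutions(row)
        except OverflowError:
            logger.warning("em_haplotype_freqs: sample genotype with too many "
                           "phase resolutions dropped (%d samples)", cnt)
            continue
        h1 = np.array([p[0] for p in pairs], dtype=int)
        h2 = np.array([p[1] for p in pairs], dtype=int)
        res_list.append((h1, h2, cnt))
        n_used += cnt

    freqs = np.full(n_hap, 1.0 / n_hap)
    # start from linkage-equilibrium products of observed allele frequencies
    p1 = np.nanmean(g, axis=0) / 2.0
    hap_bits = ((np.arange(n_hap)[:, None]
                 >> np.arange(k - 1, -1, -1)[None, :]) & 1)
    freqs = np.prod(np.where(hap_bits == 1, p1, 1 - p1), axis=1)
    freqs = np.clip(freqs, 1e-12, None)
    freqs /= freqs.sum()

    ll_prev = -np.inf
    ll = ll_prev
    for _ in range(max_iter):
        counts = np.zeros(n_hap)
        ll = 0.0
        for h1, h2, cnt in res_list:
            w = freqs[h1] * freqs[h2]
            tot = w.sum()
            if tot <= 0:
                continue
            ll += cnt * np.log(tot)
            w = (cnt / tot) * w
            np.add.at(counts, h1, w)
            np.add.at(counts, h2, w)
        freqs = counts / counts.sum()
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            break
        ll_prev = ll
    return _freq_table(snp_ids, freqs, 2 * n_used, float(ll), k)


def _freq_table(snp_ids, freqs, n_chrom, ll, k) -> HaplotypeFreqTable:
    order = np.argsort(-freqs, kind="stable")
    keep = [int(i) for i in order if freqs[i] > 1e-10]
    strings = [format(i, f"0{k}b") for i in keep]
    return HaplotypeFreqTable(snp_ids=list(snp_ids), haplotypes=strings,
                              frequencies=np.asarray(freqs)[keep],
                              n_chromosomes=n_chrom, log_likelihood=ll)


def em_two_locus(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-12,
                 max_iter: int = 500) -> tuple[float, float, float]:
    """Two-locus EM from dosage vectors; returns (p_AB, p_A, p_B).

    The only ambiguous configuration is the double heterozygote; its
    expected split between coupling (AB/ab) and repulsion (Ab/aB) phase is
    iterated to convergence.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    g1, g2 = g1[ok], g2[ok]
    n = g1.size
    if n == 0:
        raise UndefinedLDError("no pairwise-complete genotypes")
    dh = (g1 == 1) & (g2 == 1)
    n_dh = int(dh.sum())
    a, b = g1[~dh], g2[~dh]
    # unambiguous haplotype counts from the eight single-phase genotype cells
    c11 = c10 = c01 = c00 = 0.0
    for ga, gb in zip(a, b):
        la = [1] * int(ga) + [0] * (2 - int(ga))
        lb = [1] * int(gb) + [0] * (2 - int(gb))
        if ga == 1:        # locus 2 is homozygous here
            pairs = [(1, lb[0]), (0, lb[1])]
        elif gb == 1:
            pairs = [(la[0], 1), (la[1], 0)]
        else:
            pairs = [(la[0], lb[0]), (la[1], lb[1])]
        for ha, hb in pairs:
            if ha and hb:
                c11 += 1
            elif ha:
                c10 += 1
            elif hb:
                c01 += 1
            else:
                c00 += 1
    total = 2.0 * n
    f11 = (c11 + 0.5 * n_dh) / total
    f10 = (c10 + 0.5 * n_dh) / total
    f01 = (c01 + 0.5 * n_dh) / total
    f00 = (c00 + 0.5 * n_dh) / total
    for _ in range(max_iter):
        coup = f11 * f00
        rep = f10 * f01
        denom = coup + rep
        x = n_dh * (coup / denom) if denom > 0 else 0.5 * n_dh
        f11_new = (c11 + x) / total
        f00_new = (c00 + x) / total
        f10_new = (c10 + n_dh - x) / total
        f01_new = (c01 + n_dh - x) / total
        if abs(f11_new - f11) < tol:
            f11, f10, f01, f00 = f11_new, f10_new, f01_new, f00_new
            break
        f11, f10, f01, f00 = f11_new, f10_new, f01_new, f00_new
    return float(f11), float(f11 + f10), float(f11 + f01)


# ---------------------------------------------------------------------------
# D' confidence intervals and block detection
# ---------------------------------------------------------------------------

def dprime_ci(panel: GenotypePanel, snp_i: str, snp_j: str,
              confidence: float = 0.90,
              grid_step: float = 0.001) -> tuple[float, float]:
    """Profile-likelihood confidence interval for D' of a SNP pair.

    At the observed allele frequencies, two-locus haplotype frequencies
    are re-parameterised by D' on a grid over [0, 1] (sign fixed at the
    EM estimate's sign) and the genotype log-likelihood under HWE is
    profiled; the interval holds all D' within the chi-square(1) drop
    from the maximum.
    """
    gi = panel.dosages[:, panel.variant_index(snp_i)]
    gj = panel.dosages[:, panel.variant_index(snp_j)]
    ok = ~np.isnan(gi) & ~np.isnan(gj)
    gi, gj = gi[ok], gj[ok]
    if gi.size < 4 or np.var(gi) == 0 or np.var(gj) == 0:
        raise UndefinedLDError(f"LD undefined for pair ({snp_i}, {snp_j})")
    p_ab, p_a, p_b = em_two_locus(gi, gj)
    d_hat = p_ab - p_a * p_b
    sign = -1.0 if d_hat < 0 else 1.0
    if sign > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max <= 0:
        raise UndefinedLDError("degenerate allele frequencies")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    d = sign * grid * d_max
    f11 = np.clip(p_a * p_b + d, 0.0, 1.0)
    f10 = np.clip(p_a * (1 - p_b) - d, 0.0, 1.0)
    f01 = np.clip((1 - p_a) * p_b - d, 0.0, 1.0)
    f00 = np.clip((1 - p_a) * (1 - p_b) + d, 0.0, 1.0)
    # genotype-cell counts (3 x 3)
    counts = np.zeros((3, 3))
    for a, b in zip(gi.astype(int), gj.astype(int)):
        counts[a, b] += 1
    probs = np.empty((grid.size, 3, 3))
    probs[:, 0, 0] = f00 ** 2
    probs[:, 0, 1] = 2 * f00 * f01
    probs[:, 0, 2] = f01 ** 2
    probs[:, 1, 0] = 2 * f00 * f10
    probs[:, 1, 1] = 2 * (f11 * f00 + f10 * f01)
    probs[:, 1, 2] = 2 * f01 * f11
    probs[:, 2, 0] = f10 ** 2
    probs[:, 2, 1] = 2 * f10 * f11
    probs[:, 2, 2] = f11 ** 2
    with np.errstate(divide="ignore"):
        logp = np.log(np.clip(probs, 1e-300, None))
    ll = np.tensordot(logp, counts, axes=([1, 2], [0, 1]))
    drop = stats.chi2.ppf(confidence, df=1) / 2.0
    inside = ll >= ll.max() - drop
    return float(grid[inside].min()), float(grid[inside].max())


def _pair_gamete_count(panel: GenotypePanel, i: int, j: int,
                       min_freq: float = 0.01) -> int:
    """Number of the four two-locus gametes present at >= min_freq."""
    if panel.phased:
        hi = panel.haplotypes[:, i]
        hj = panel.haplotypes[:, j]
        ok = ~np.isnan(hi) & ~np.isnan(hj)
        code = 2 * hi[ok].astype(int) + hj[ok].astype(int)
        freqs = np.bincount(code, minlength=4) / max(ok.sum(), 1)
        return int(np.sum(freqs >= min_freq))
    f11, p_a, p_b = em_two_locus(panel.dosages[:, i], panel.dosages[:, j])
    freqs = np.array([(1 - p_a) * (1 - p_b) + f11 - p_a * p_b,
                      p_b - f11,
                      p_a - f11,
                      f11])
    return int(np.sum(freqs >= min_freq))


def find_blocks(panel: GenotypePanel, method: str = "gabriel",
                params: dict | None = None) -> list[Block]:
    """Detect haplotype blocks over one chromosome of a panel.

    ``gabriel``: pairs are strong when the D' CI satisfies
    low >= ``ci_low_min`` (0.70) and high >= ``ci_high_min`` (0.98);
    a span is a block when >= ``strong_frac`` (0.95) of its informative
    pairs are strong; maximal non-overlapping blocks are chosen greedily
    by bp span length, ties to the leftmost.

    ``four_gamete``: greedy maximal runs in which every internal pair
    shows at most 3 of the 4 gametes at frequency >= ``min_freq`` (0.01).
    """
    params = dict(params or {})
    m = panel.n_variants
    if m < 2:
        raise ValueError("block detection requires >= 2 SNPs")
    chroms = {v.chrom for v in panel.variants}
    if len(chroms) != 1:
        raise ValueError("block detection expects a single-chromosome panel")
    chrom = chroms.pop()
    pos = panel.positions

    if method == "gabriel":
        ci_low_min = params.pop("ci_low_min", 0.70)
        ci_high_min = params.pop("ci_high_min", 0.98)
        strong_frac = params.pop("strong_frac", 0.95)
        confidence = params.pop("confidence", 0.90)
        strong = np.zeros((m, m), dtype=bool)
        informative = np.zeros((m, m), dtype=bool)
        ids = panel.variant_ids
        for i in range(m):
            for j in range(i + 1, m):
                try:
                    lo, hi = dprime_ci(panel, ids[i], ids[j],
                                       confidence=confidence)
                except UndefinedLDError:
                    continue
                informative[i, j] = True
                strong[i, j] = lo >= ci_low_min and hi >= ci_high_min
        candidates = []
        for i in range(m):
            for j in range(i + 1, m):
                info = informative[i:j + 1, i:j + 1].sum()
                if info == 0:
                    continue
                if strong[i:j + 1, i:j + 1].sum() / info >= strong_frac:
                    candidates.append((pos[j] - pos[i], i, j))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        taken = np.zeros(m, dtype=bool)
        blocks = []
        for _, i, j in candidates:
            if taken[i:j + 1].any():
                continue
            taken[i:j + 1] = True
            blocks.append(Block(chrom=chrom, start_bp=int(pos[i]),
                                end_bp=int(pos[j]),
                                snp_ids=panel.variant_ids[i:j + 1]))
    elif method == "four_gamete":
        min_freq = params.pop("min_freq", 0.01)
        ok_pair = {}

        def pair_ok(i: int, j: int) -> bool:
            if (i, j) not in ok_pair:
                try:
                    ok_pair[(i, j)] = _pair_gamete_count(
                        panel, i, j, min_freq) <= 3
                except UndefinedLDError:
                    ok_pair[(i, j)] = False
            return ok_pair[(i, j)]

        blocks = []
        i = 0
        while i < m - 1:
            j = i
            while j + 1 < m and all(pair_ok(t, j + 1) for t in range(i, j + 1)):
                j += 1
            if j > i:
                blocks.append(Block(chrom=chrom, start_bp=int(pos[i]),
                                    end_bp=int(pos[j]),
                                    snp_ids=panel.variant_ids[i:j + 1]))
                i = j + 1
            else:
                i += 1
    else:
        raise ValueError(f"unknown block method {method!r}")
    blocks.sort(key=lambda blk: blk.start_bp)
    return blocks


def write_blocks_bed(blocks: list[Block], path: str) -> None:
    """BED-like block report (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for idx, blk in enumerate(blocks, start=1):
            fh.write(f"{blk.chrom}\t{blk.start_bp - 1}\t{blk.end_bp}\t"
                     f"block{idx}\t{blk.n_snps}\n")


# ---------------------------------------------------------------------------
# tag SNP selection
# ---------------------------------------------------------------------------

def select_tags(ld, r2_threshold: float = 0.8) -> TagSet:
    """Greedy tag-SNP selection on an LD matrix.

    Repeatedly picks the SNP covering the most still-uncovered SNPs at
    r2 >= threshold (ties to the lower position index) until every SNP is
    covered; a SNP always covers itself.
    """
    r2 = ld.r2
    m = r2.shape[0]
    covered = np.zeros(m, dtype=bool)
    cover = r2 >= r2_threshold
    np.fill_diagonal(cover, True)
    tags: list[int] = []
    while not covered.all():
        gains = cover[:, ~covered].sum(axis=1)
        best = int(np.argmax(gains))        # argmax takes the lowest index tie
        tags.append(best)
        covered |= cover[best]
    tag_ids = [ld.variant_ids[t] for t in tags]
    coverage: dict[str, tuple[str, float]] = {}
    for s in range(m):
        if s in tags:
            continue
        best_tag = max(tags, key=lambda t: r2[t, s])
        coverage[ld.variant_ids[s]] = (ld.variant_ids[best_tag],
                                       float(r2[best_tag, s]))
    return TagSet(tags=tag_ids, r2_threshold=r2_threshold,
                  coverage_map=coverage)
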