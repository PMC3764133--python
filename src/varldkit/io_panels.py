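"""Reading, validation, harmonization and subsetting of genotype panels.

All coordinates are 1-based inclusive, matching VCF convention.  Genotypes
are held as allele-b dosages (count of the `allele_b` nucleotide, 0/1/2) in
a float matrix with ``NaN`` marking missing calls; phased panels carry an
additional 2n x m binary haplotype matrix in which rows ``2i`` and ``2i+1``
are the two haplotypes of individual ``i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import HarmonizationError, LookupError_, PanelError, ParseError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Metadata columns of the full HapMap genotype-table dialect that are not
#: per-sample genotypes.
HAPMAP_META_COLUMNS = frozenset(
    {"strand", "assembly#", "assembly", "center", "protLSID", "assayLSID",
     "panelLSID", "QCcode", "QC_code"}
)


@dataclass(frozen=True)
class Variant:
    """One biallelic SNP.

    ``allele_b`` is the allele counted by the dosage matrix (ALT for VCF
    input, the second declared allele for HapMap tables).
    """

    id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if not self.id:
            raise PanelError("variant id must be non-empty")
        if self.pos < 1:
            raise PanelError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        for a in (self.allele_a, self.allele_b):
            if a not in VALID_ALLELES:
                raise PanelError(f"variant {self.id}: invalid allele {a!r}")
        if self.allele_a == self.allele_b:
            raise PanelError(f"variant {self.id}: alleles must differ")

    @property
    def is_strand_ambiguous(self) -> bool:
        """A/T and C/G SNPs cannot be strand-resolved from allele labels."""
        return COMPLEMENT[self.allele_a] == self.allele_b


@dataclass
class RegionSpec:
    """A genomic region, 1-based inclusive, optionally padded symmetrically."""

    chrom: str
    start_bp: int
    end_bp: int
    pad_bp: int = 0

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"start_bp {self.start_bp} > end_bp {self.end_bp}")
        if self.pad_bp < 0:
            raise ValueError("pad_bp must be >= 0")

    @property
    def padded_start(self) -> int:
        return self.start_bp - self.pad_bp

    @property
    def padded_end(self) -> int:
        return self.end_bp + self.pad_bp

    @classmethod
    def from_string(cls, s: str, pad_bp: int = 0) -> "RegionSpec":
        """Parse ``chr:start-end``; ``Mb`` suffixes on bounds are accepted."""
        try:
            chrom, rng = s.split(":")
            lo, hi = rng.split("-")

            def _bp(tok: str) -> int:
                tok = tok.strip().replace(",", "")
                if tok.lower().endswith("mb"):
                    return int(round(float(tok[:-2]) * 1_000_000))
                return int(tok)

            return cls(chrom=chrom, start_bp=_bp(lo), end_bp=_bp(hi), pad_bp=pad_bp)
        except ValueError as exc:
            raise ParseError(f"cannot parse region string {s!r}") from exc


@dataclass
class GenotypePanel:
    """A per-population sample-by-variant dosage panel.

    Invariants (checked on construction):

    * variants strictly increasing by (chrom, pos), unique ids;
    * every variant has at least one non-missing observation;
    * if phased, haplotype pair sums equal dosages wherever both are
      non-missing.
    """

    population: str
    variants: list[Variant]
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None
    phased: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise PanelError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise PanelError(
                f"dosage columns ({self.dosages.shape[1]}) != number of "
                f"variants ({len(self.variants)})"
            )
        if len(self.variants) == 0:
            raise PanelError(f"panel {self.population!r} has no variants")
        keys = [(v.chrom, v.pos, v.allele_a, v.allele_b) for v in self.variants]
        if len(set(keys)) != len(keys):
            raise PanelError("duplicate (chrom, pos, alleles) in panel")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate variant ids in panel")
        by_chrom: dict[str, int] = {}
        for v in self.variants:
            prev = by_chrom.get(v.chrom)
            if prev is not None and v.pos <= prev:
                raise PanelError("variants not strictly increasing by position")
            by_chrom[v.chrom] = v.pos
        obs = np.sum(~np.isnan(self.dosages), axis=0)
        if np.any(obs == 0):
            bad = [ids[i] for i in np.flatnonzero(obs == 0)]
            raise PanelError(f"variants with no observations: {bad}")
        if self.phased:
            if self.haplotypes is None:
                raise PanelError("phased panel requires a haplotype matrix")
            self.haplotypes = np.asarray(self.haplotypes, dtype=float)
            if self.haplotypes.shape != (2 * self.dosages.shape[0],
                                         self.dosages.shape[1]):
                raise PanelError("haplotype matrix must be 2*n_samples x n_variants")
            hsum = self.haplotypes[0::2] + self.haplotypes[1::2]
            both = ~np.isnan(hsum) & ~np.isnan(self.dosages)
            if not np.allclose(hsum[both], self.dosages[both]):
                raise PanelError("haplotype pair sums disagree with dosages")
        self._index = {v.id: i for i, v in enumerate(self.variants)}

    # -- basic views ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise LookupError_(
                f"variant {variant_id!r} not in panel {self.population!r}"
            ) from None

    def subset_variants(self, indices: np.ndarray | list[int]) -> "GenotypePanel":
        """New panel restricted to variant columns ``indices`` (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return GenotypePanel(
            population=self.population,
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
            phased=self.phased,
        )

    def subset_samples(self, indices: np.ndarray | list[int],
                       population: str | None = None) -> "GenotypePanel":
        idx = np.asarray(indices, dtype=int)
        hap = None
        if self.haplotypes is not None:
            hap_idx = np.empty(2 * len(idx), dtype=int)
            hap_idx[0::2] = 2 * idx
            hap_idx[1::2] = 2 * idx + 1
            hap = self.haplotypes[hap_idx]
        return GenotypePanel(
            population=population or self.population,
            variants=list(self.variants),
            dosages=self.dosages[idx],
            haplotypes=hap,
            phased=self.phased,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_vcf(path: str, population: str,
             samples: list[str] | None = None) -> GenotypePanel:
    """Read diploid genotypes from a VCF into a :class:`GenotypePanel`.

    Multi-allelic and non-SNP records are skipped (counted in the log).
    ``phased`` is set only when every retained non-missing genotype carries
    a phase separator.  ``samples`` optionally restricts to a subset of
    sample IDs (e.g. unrelated founders of trio panels).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), samples=samples)
    except OSError as exc:
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    sample_names = vcf.samples
    n = len(sample_names)
    variants: list[Variant] = []
    dosage_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    skipped = 0
    all_phased = True
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.REF not in VALID_ALLELES \
                or rec.ALT[0] not in VALID_ALLELES:
            skipped += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(Variant(id=vid, chrom=str(rec.CHROM), pos=rec.POS,
                                allele_a=rec.REF, allele_b=rec.ALT[0]))
        dcol = np.full(n, np.nan)
        hcol = np.full(2 * n, np.nan)
        for i, gt in enumerate(rec.genotypes):
            a0, a1, ph = gt[0], gt[1], gt[2]
            if a0 < 0 or a1 < 0:
                continue
            dcol[i] = a0 + a1
            hcol[2 * i] = a0
            hcol[2 * i + 1] = a1
            if not ph:
                all_phased = False
        dosage_cols.append(dcol)
        hap_cols.append(hcol)
    vcf.close()
    if skipped:
        logger.info("read_vcf(%s): skipped %d multi-allelic/non-SNP records",
                    path, skipped)
    if not variants:
        raise PanelError(f"no biallelic SNPs retained from {path}")
    dosages = np.column_stack(dosage_cols)
    phased = all_phased
    haplotypes = np.column_stack(hap_cols) if phased else None
    return GenotypePanel(population=population, variants=variants,
                         dosages=dosages, haplotypes=haplotypes, phased=phased)


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write a panel as an uncompressed VCF 4.2 file (SNP records only)."""
    n = panel.n_samples
    names = [f"{panel.population}_{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in panel.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        sep = "|" if panel.phased else "/"
        for j, v in enumerate(panel.variants):
            gts = []
            for i in range(n):
                d = panel.dosages[i, j]
                if np.isnan(d):
                    gts.append(f".{sep}.")
                elif panel.phased:
                    h0 = int(panel.haplotypes[2 * i, j])
                    h1 = int(panel.haplotypes[2 * i + 1, j])
                    gts.append(f"{h0}|{h1}")
                else:
                    d = int(d)
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.allele_a}\t{v.allele_b}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_hapmap_table(path: str, population: str) -> GenotypePanel:
    """Read a HapMap-style whitespace-delimited genotype table.

    Layout: ``rs# alleles chrom pos [metadata...] sample1 sample2 ...``
    with genotype strings like ``AG``; ``NN`` is missing.  Dosage counts
    copies of the second declared allele.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.shape[1] < 5:
        raise ParseError(f"{path}: expected >= 5 columns (4 metadata + samples)")
    sample_cols = [c for c in df.columns[4:] if c not in HAPMAP_META_COLUMNS]
    variants: list[Variant] = []
    cols: list[np.ndarray] = []
    for ridx, row in df.iterrows():
        vid, alleles, chrom, pos = (row.iloc[0], row.iloc[1],
                                    str(row.iloc[2]), int(row.iloc[3]))
        chrom = chrom.removeprefix("chr")
        try:
            a_a, a_b = alleles.split("/")
        except ValueError:
            raise ParseError(f"{path} row {ridx}: bad allele field {alleles!r}")
        variants.append(Variant(id=vid, chrom=chrom, pos=pos,
                                allele_a=a_a, allele_b=a_b))
        dcol = np.full(len(sample_cols), np.nan)
        for i, sc in enumerate(sample_cols):
            g = str(row[sc]).upper()
            if g == "NN":
                continue
            if len(g) != 2 or any(ch not in (a_a, a_b) for ch in g):
                raise ParseError(
                    f"{path} row {ridx} ({vid}), sample {sc}: genotype {g!r} "
                    f"not composed of declared alleles {a_a}/{a_b}"
                )
            dcol[i] = g.count(a_b)
        cols.append(dcol)
    if not variants:
        raise PanelError(f"no SNPs in {path}")
    order = np.lexsort(([v.pos for v in variants], [v.chrom for v in variants]))
    variants = [variants[i] for i in order]
    dosages = np.column_stack([cols[i] for i in order])
    return GenotypePanel(population=population, variants=variants,
                         dosages=dosages, phased=False)


def write_hapmap_table(panel: GenotypePanel, path: str) -> None:
    """Write a panel as a 4-metadata-column HapMap-style genotype table."""
    names = [f"{panel.population}_{i}" for i in range(panel.n_samples)]
    with open(path, "w") as fh:
        fh.write("rs# alleles chrom pos " + " ".join(names) + "\n")
        for j, v in enumerate(panel.variants):
            gts = []
            for i in range(panel.n_samples):
                d = panel.dosages[i, j]
                if np.isnan(d):
                    gts.append("NN")
                else:
                    d = int(d)
                    gts.append(v.allele_a * (2 - d) + v.allele_b * d)
            fh.write(f"{v.id} {v.allele_a}/{v.allele_b} {v.chrom} {v.pos} "
                     + " ".join(gts) + "\n")


def read_sample_list(path: str) -> list[str]:
    """Read a sample-ID list, one per line, blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# region and harmonization operations
# ---------------------------------------------------------------------------

def extract_region(panel: GenotypePanel, region: RegionSpec) -> GenotypePanel:
    """Subset to variants inside the padded region (1-based inclusive).

    An empty result is allowed and returned as ``None``-free empty subset
    is impossible for :class:`GenotypePanel`; callers receive a
    :class:`PanelError` only when zero SNPs survive, mirroring an empty
    panel, after a logged warning.
    """
    keep = [i for i, v in enumerate(panel.variants)
            if v.chrom == region.chrom
            and region.padded_start <= v.pos <= region.padded_end]
    if not keep:
        logger.warning("extract_region: no SNPs of %s in %s:%d-%d (pad %d)",
                       panel.population, region.chrom, region.start_bp,
                       region.end_bp, region.pad_bp)
        raise PanelError(
            f"no SNPs of panel {panel.population!r} in region "
            f"{region.chrom}:{region.padded_start}-{region.padded_end}"
        )
    return panel.subset_variants(keep)


def allele_frequency(panel: GenotypePanel, variant_id: str) -> float:
    """Frequency of ``allele_b`` among non-missing alleles; in [0, 1]."""
    j = panel.variant_index(variant_id)
    col = panel.dosages[:, j]
    ok = ~np.isnan(col)
    return float(np.sum(col[ok]) / (2.0 * np.sum(ok)))


def _maf(panel: GenotypePanel, j: int) -> float:
    col = panel.dosages[:, j]
    ok = ~np.isnan(col)
    f = np.sum(col[ok]) / (2.0 * np.sum(ok))
    return min(f, 1.0 - f)


def _flip_variant(panel: GenotypePanel, j: int) -> None:
    """Swap allele labels at column ``j`` in place: dosage d -> 2 - d."""
    v = panel.variants[j]
    panel.variants[j] = replace(v, allele_a=v.allele_b, allele_b=v.allele_a)
    panel.dosages[:, j] = 2.0 - panel.dosages[:, j]
    if panel.haplotypes is not None:
        panel.haplotypes[:, j] = 1.0 - panel.haplotypes[:, j]


def harmonize_panels(p1: GenotypePanel, p2: GenotypePanel,
                     maf_min: float = 0.01) -> tuple[GenotypePanel, GenotypePanel]:
    """Reduce two panels to a shared, allele-aligned variant list.

    Variants are matched by (chrom, pos).  Allele labels are aligned so
    ``allele_b`` means the same nucleotide in both panels (flipping dosages
    ``d -> 2 - d`` when sources disagree); opposite-strand reports are
    reconciled by complementing, except that strand-ambiguous A/T and C/G
    SNPs with discordant allele sets are dropped.  Variants monomorphic or
    with MAF < ``maf_min`` in either panel are dropped.
    """
    pos2 = {(v.chrom, v.pos): j for j, v in enumerate(p2.variants)}
    keep1: list[int] = []
    keep2: list[int] = []
    flip2: list[int] = []
    n_strand_dropped = 0
    for i, v1 in enumerate(p1.variants):
        j = pos2.get((v1.chrom, v1.pos))
        if j is None:
            continue
        v2 = p2.variants[j]
        s1 = {v1.allele_a, v1.allele_b}
        s2 = {v2.allele_a, v2.allele_b}
        if s1 == s2:
            flip = v1.allele_b != v2.allele_b
        else:
            if v1.is_strand_ambiguous or v2.is_strand_ambiguous:
                n_strand_dropped += 1
                continue
            s2c = {COMPLEMENT[v2.allele_a], COMPLEMENT[v2.allele_b]}
            if s1 != s2c:
                logger.info("harmonize: allele mismatch at %s:%d dropped",
                            v1.chrom, v1.pos)
                continue
            flip = v1.allele_b != COMPLEMENT[v2.allele_b]
        keep1.append(i)
        keep2.append(j)
        if flip:
            flip2.append(len(keep2) - 1)
    if n_strand_dropped:
        logger.info("harmonize: dropped %d strand-ambiguous discordant SNPs",
                    n_strand_dropped)
    if not keep1:
        raise HarmonizationError(
            f"panels {p1.population!r} and {p2.population!r} share no SNPs"
        )
    out1 = p1.subset_variants(keep1)
    out2 = p2.subset_variants(keep2)
    for k in flip2:
        _flip_variant(out2, k)
    # unify ids on the first panel's naming
    out2.variants = list(out1.variants) if all(
        va.allele_a == vb.allele_a and va.allele_b == vb.allele_b
        for va, vb in zip(out1.variants, out2.variants)) else out2.variants
    out2._index = {v.id: i for i, v in enumerate(out2.variants)}
    keep = [k for k in range(out1.n_variants)
            if _maf(out1, k) >= maf_min and _maf(out2, k) >= maf_min
            and _maf(out1, k) > 0 and _maf(out2, k) > 0]
    if not keep:
        raise HarmonizationError(
            "no SNPs remain after MAF filtering during harmonization"
        )
    if len(keep) < out1.n_variants:
        logger.info("harmonize: dropped %d monomorphic/low-MAF SNPs",
                    out1.n_variants - len(keep))
    return out1.subset_variants(keep), out2.subset_variants(keep)
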