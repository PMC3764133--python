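"""Reference coordinates for the LRRK2 region on chromosome 12 (NCBI
build 36) and the PD-associated SNPs reported there by genome-wide
association studies in Japanese and Caucasian cohorts.

These constants let region handling and focal-SNP distance computations
run without external downloads.
"""

from __future__ import annotations

from .io_panels import RegionSpec

#: LRRK2 analysis region: gene neighbourhood extended by 10 kb on each side.
LRRK2_REGION = RegionSpec(chrom="12", start_bp=38_715_000, end_bp=39_039_000,
                          pad_bp=10_000)

#: PD-associated SNPs in/near LRRK2 (build-36 positions): id -> (pos, cohort).
GWAS_SNPS: dict[str, tuple[int, str]] = {
    "rs1994090": (38_714_828, "Japanese"),
    "rs11564162": (38_729_159, "Caucasian"),
    "rs7304279": (38_752_209, "Japanese"),
    "rs4768212": (38_760_414, "Japanese"),
    "rs2708453": (38_764_919, "Japanese"),
    "rs2896905": (38_779_683, "Caucasian"),
    "rs2046932": (38_866_707, "Japanese"),
    "rs1491923": (38_877_384, "Caucasian"),
}


def snp_distance_kb(snp_a: str, snp_b: str, ndigits: int = 1) -> float:
    """Distance between two reference SNPs in kb, rounded to ``ndigits``."""
    pa = GWAS_SNPS[snp_a][0]
    pb = GWAS_SNPS[snp_b][0]
    return round(abs(pa - pb) / 1000.0, ndigits)
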