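"""The varLD regional LD-dissimilarity score.

For two populations genotyped at the same m SNPs, each population's signed
correlation LD matrix is eigendecomposed and the score is the sum of
absolute differences between the two rank-ordered (descending) eigenvalue
spectra:

    score = sum_i | lambda_1(i) - lambda_2(i) |

The score is non-negative, zero iff the spectra coincide, invariant under
per-SNP allele recoding (which conjugates an LD matrix by a +/-1 diagonal
matrix), and bounded by 2m because each spectrum sums to the trace m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_panels import GenotypePanel
from .ld import LDMatrix, ld_matrix

SYMMETRY_ATOL = 1e-8


@dataclass
class VarLDScore:
    """Raw regional varLD score with the eigenvalue spectra behind it."""

    score: float
    eigenvalues_1: np.ndarray
    eigenvalues_2: np.ndarray
    m: int
    window_id: int | None = None
    variant_ids: list[str] | None = None


def eigenvalues_sorted(ld: LDMatrix | np.ndarray) -> np.ndarray:
    """Descending-ordered real eigenvalues of a symmetric LD matrix."""
    a = ld.r_signed if isinstance(ld, LDMatrix) else np.asarray(ld, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("LD matrix must be square")
    if not np.allclose(a, a.T, atol=SYMMETRY_ATOL):
        raise ValueError("LD matrix is not symmetric within tolerance")
    lam = np.linalg.eigvalsh(a)
    return lam[::-1]


def varld_raw_score(ld1: LDMatrix, ld2: LDMatrix) -> VarLDScore:
    """Raw varLD score between two same-SNP-list LD matrices."""
    if ld1.variant_ids != ld2.variant_ids:
        raise ValueError(
            "LD matrices cover different SNP lists; harmonize the panels "
            "(io_panels.harmonize_panels) before scoring"
        )
    lam1 = eigenvalues_sorted(ld1)
    lam2 = eigenvalues_sorted(ld2)
    return VarLDScore(
        score=float(np.abs(lam1 - lam2).sum()),
        eigenvalues_1=lam1,
        eigenvalues_2=lam2,
        m=ld1.m,
        variant_ids=list(ld1.variant_ids),
    )


def varld_score_from_matrices(r1: np.ndarray, r2: np.ndarray) -> float:
    """Score straight from two signed-r arrays (internal fast path)."""
    lam1 = np.linalg.eigvalsh(r1)
    lam2 = np.linalg.eigvalsh(r2)
    return float(np.abs(lam1 - lam2).sum())


def varld_windows(p1: GenotypePanel, p2: GenotypePanel, window_snps: int,
                  step_snps: int, mode: str = "auto") -> list[VarLDScore]:
    """Sliding-window varLD scores over harmonized panels.

    Windows hold ``window_snps`` consecutive common SNPs advanced by
    ``step_snps``; a final partial window is dropped.  With
    ``window_snps = m`` this degenerates to the single regional score.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if p1.variant_ids != p2.variant_ids:
        raise ValueError("panels must be harmonized to a common SNP list")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")
    m = p1.n_variants
    if window_snps > m:
        raise ValueError(f"window_snps {window_snps} exceeds m={m}")
    out: list[VarLDScore] = []
    wid = 0
    for start in range(0, m - window_snps + 1, step_snps):
        idx = list(range(start, start + window_snps))
        s = varld_raw_score(ld_matrix(p1.subset_variants(idx), mode=mode),
                            ld_matrix(p2.subset_variants(idx), mode=mode))
        s.window_id = wid
        out.append(s)
        wid += 1
    return out


def standardize_scores(scores: np.ndarray) -> np.ndarray:
    """Z-standardize a score vector to mean 0, unit (population) SD."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need >= 2 scores to standardize")
    sd = s.std()
    if sd == 0:
        raise ValueError("scores have zero variance")
    return (s - s.mean()) / sd
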