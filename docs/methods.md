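# Methods

## Panels, coordinates and harmonization

A `GenotypePanel` is one population's sample-by-SNP allele-b dosage
matrix (0/1/2, `NaN` missing), optionally with a 2n × m binary haplotype
matrix when phased. Coordinates are 1-based inclusive everywhere,
matching VCF and the usual SNP-table convention; region extraction is
inclusive at both ends and supports a symmetric pad (the *LRRK2*
reference region is the gene neighbourhood padded by 10 kb,
chr12:38,705,000–39,049,000 on build 36).

Any cross-population comparison first harmonizes the two panels:
variants are matched by (chrom, pos), allele labels aligned so that
allele b denotes the same nucleotide in both (flipping dosages d → 2−d
when the sources label alleles in opposite order, complementing when
they report opposite strands). Strand-ambiguous A/T and C/G SNPs whose
allele sets disagree cannot be safely oriented and are dropped rather
than frequency-matched — a deliberate safety-over-coverage choice at
regional scale. SNPs monomorphic or below the MAF floor (default 0.01;
r is undefined at MAF 0) in either panel are removed. Pedigrees are not
modelled; trio panels should be restricted to founders via the sample
list accepted by the VCF reader.

## LD statistics

Pairwise LD comes in three modes, and a comparison must use one mode for
both populations:

* `haplotype_counted` (default for phased panels): haplotype frequencies
  counted directly; D = p_AB − p_A p_B, r = D/√(p_A q_A p_B q_B),
  D′ = |D|/D_max with the sign-dependent bound.
* `genotype_corr` (default for unphased panels): the composite Pearson
  correlation of dosage vectors. It converges to the haplotype r under
  Hardy–Weinberg equilibrium and is the statistic the varLD approach
  consumes for genotype data; D and D′ are not defined in this mode.
* `haplotype_em`: two-locus haplotype frequencies estimated by EM from
  unphased genotypes, then the haplotype formulas.

Missing data are handled by pairwise-complete deletion. A pair with
fewer than 4 complete observations or a monomorphic locus has undefined
LD; inside a matrix such entries are set to r = 0 (logged) so that the
eigendecomposition never sees NaN, and a strict mode raises instead.
Matrices zero-filled this way are not re-projected to positive
semidefinite: the score uses ordered eigenvalue differences only, and
slightly negative eigenvalues are harmless there.

## The varLD score and its permutation test

The regional score is the L1 distance between the descending-ordered
eigenvalue spectra of the two populations' signed-r matrices. A single
region-wide window is the default — the targeted analysis reports one
score per population pair — with an optional sliding window
(`varld_windows`) and a z-standardization utility for users who scan
many windows. Raw scores feed the permutation test directly:
standardization is monotone and therefore irrelevant under permutation.

The null "both samples come from one population" is tested by pooling
the panels and re-partitioning whole individuals (both haplotypes move
together, i.e. a permutation of population labels, without replacement)
into the original sample sizes B times. The estimator
p = (1 + #{replicate ≥ observed})/(1 + B) is strictly positive, floors
at 1/(B+1), and counts ties conservatively (≥, not >). Permutation gives
exact finite-sample validity, which is why label permutation was chosen
over a bootstrap. With no missing data the replicate loop runs on a
vectorised matrix-algebra path; with missing data it falls back to the
panel-based path, pairwise-complete per replicate.

Multi-pair runs derive one RNG sub-stream per pair from the table seed,
so any row can be recomputed independently. Bonferroni control is strict
(p exactly at α/n is not significant). Pooled groups (e.g. an "Asian"
panel) are built by multi-way harmonization of the members to their
common SNP set followed by row concatenation; pooling was chosen over
averaging pairwise comparisons as the more direct reading of a merged
reference group.

## Haplotype analysis

Multilocus haplotype frequencies for 2–12 SNPs use the classical EM
under HWE: each ambiguous multilocus genotype distributes its mass over
consistent ordered haplotype pairs proportionally to current frequency
products; the M-step renormalises expected counts. Initialisation is at
linkage-equilibrium products of the observed allele frequencies,
tolerance 1e−7 on the log-likelihood, max 1000 iterations; restarts are
not used because the likelihood surface is well-behaved at k ≤ 12 and
these sample sizes. Phased panels bypass the EM entirely (direct
counting, which the EM must and does reproduce when phase is
unambiguous). The "common haplotype" report threshold is 5%.

D′ confidence intervals are profile-likelihood intervals: with allele
frequencies fixed at their estimates, the two-locus genotype
log-likelihood under HWE is evaluated on a D′ grid (step 0.001, sign
fixed at the EM estimate's sign) and the interval keeps all D′ within
the χ²₁ drop for the requested confidence (default 0.90).

Blocks use the D′-CI construction as the de facto standard: a pair is
"strong LD" when CI-low ≥ 0.70 and CI-high ≥ 0.98; a candidate span is a
block when ≥ 95% of its informative pairs are strong; maximal
non-overlapping blocks are chosen greedily by bp span, ties to the
leftmost. A four-gamete alternative (no internal pair shows all four
gametes at frequency ≥ 0.01) is provided as a cheaper method. Tag SNPs
are selected greedily: repeatedly take the SNP covering the most
uncovered SNPs at r² ≥ threshold (ties to the lower position index)
until all are covered.

## Synthetic panels

The simulator draws haplotypes through a Gaussian copula: latent
multivariate normal with a target correlation matrix, thresholded per
SNP at the normal quantile of its allele frequency; consecutive
haplotypes pair into diploid individuals. This was chosen over a
coalescent simulator because the varLD test consumes exactly an LD
matrix, and the copula gives direct, seedable control of it; the cost is
that the simulator does not reproduce coalescent features of real data
(allele-frequency spectra from drift, recombination hotspots, rare
variants, population-specific frequency differences), so passing tests
demonstrate statistical validity and power of the machinery, not
faithfulness to any particular human cohort.

Defaults emulate a desk-scale regional panel: ~120 SNPs at uniform
1.6 kb spacing from 38,705,000 bp on chromosome 12, MAF drawn uniformly
from [0.05, 0.5] and shared between the two populations (so divergence
is purely in LD), diploid sample sizes of order 80–200, AR(1) latent
correlation backbone. Divergence options: `ar1_contrast(ρ1, ρ2)` gives
the panels different decay rates; `block_permute(fraction)` permutes a
fraction of SNP labels in the second panel's target, destroying
positional LD while preserving the spectrum's scale. Targets that are
not positive definite (e.g. hand-written block matrices with within-r
= 1) are repaired by clipping eigenvalues at 1e−6 and renormalising the
diagonal, with a log message. Binary-scale correlation is attenuated
relative to the latent ρ, so all tests assert on empirical matrices,
never on latent targets.

## Operating conditions and problem sizes

The statistical validation runs at: type-I error — 400 independent null
runs (m = 20 SNPs, n = 50 + 50, B = 199), rejection rate at α = 0.05
checked against its 99% binomial band [0.025, 0.082]; power — 200 runs
of `ar1_contrast(0.9, 0.2)` (m = 30, n = 100 + 100, B = 199), requiring
≥ 0.90 rejections at α = 0.05; the p-value floor — one strongly
divergent pair (m = 20, n = 50 + 50) at B = 10,000. These sizes make the
whole suite and the acceptance script run in about a minute each on one
CPU while leaving the binomial bands tight enough to be informative.

## Numerical choices and limitations

Eigenvalues use the symmetric solver (`eigvalsh`); ordering ties are
broken by value then original index, which cannot affect the score.
Scores are printed at 6 significant figures and p-values at 4 decimals
in tabular output (full precision in machine-readable form). Known
limitations: no imputation, phasing, liftover or pedigree inference; no
genome-wide varLD percentile calibration (the per-window z-utility is
provided, genome-scale scanning is out of scope); EM haplotype
estimation is limited to 12 SNPs by 2^k enumeration; Gabriel-style block
parameters are conventions, and block coordinates on real cohorts depend
on them more strongly than the varLD score does on any of its settings.
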