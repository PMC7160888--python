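# Methods

This note documents the models, parameter choices and numerical decisions
behind `depthdiff`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Cohort and genotype model

The synthetic cohort generator (`depthdiff.synthetic`) emulates a small
case/control chip-genotyping study: 71 cases and 36 controls by default,
markers laid every 10 kbp on one chromosome and organised in LD blocks of
200 kbp. Within a block each gamete copies one of a small pool of founder
template haplotypes (6 by default) with a per-marker mutation rate of 0.01,
and recombines freely between blocks with per-block probability 0.1. This
"copy-with-recombination" structure is the simplest that makes r²-based
locus definition meaningful: markers within a block reach r² ≈ 0.85–1.0,
markers in different blocks are independent.

One designated protective marker (block-central) is drawn at group-specific
frequencies — 0.05 in cases and 0.26 in controls by default, the kind of
case-depleted haplotype a protective variant produces. Its block contains
exactly two founder haplotypes (tagged vs untagged), so the surrounding
markers tag the causal allele at high but imperfect r². The causal marker
itself is exempted from mutation noise so its realized frequencies are
exactly binomial at the configured values; its tag markers are not, which
is what keeps their r² below 1.

Optional sib-pair families (gamete sampling from simulated parents, free
recombination between blocks) induce genuine cryptic relatedness; they are
what lets the mixed model demonstrably out-calibrate the naive trend test.

Diagnostic measurements (TgAA, TSH, fT4, age) are drawn consistently with
the classification rules — case: TgAA positive and/or TSH ≥ 40 mU/l;
control: TgAA negative, TSH ≤ 25 mU/l, fT4 ≥ 5 pmol/l, age ≥ 7 years;
everything else unclassified — so `classify_phenotype` round-trips the
simulated statuses.

## Depth model

Per-base depth is Poisson with a sample-specific mean (e.g. ~46X for
high-coverage, ~6.8X for low-coverage samples) modulated by a smooth
sinusoidal GC-like trend (relative amplitude 0.05–0.1, period 20 kbp).
Deletion carriers' rate over the deletion interval is scaled by copies/2
(heterozygote 0.5, homozygote 0). Assembly gaps force depth to zero;
repeat-like q0 regions are drawn negative-binomial with doubled variance
and exported as a BED mask. This is deliberately not a read-level
simulator: there are no reads, no mapping errors, no insert sizes, no
GC-dependence beyond the smooth trend. Window means, t-tests, M-values and
depth-ratio genotyping only consume per-window depth moments, for which the
Poisson model is sufficient; conclusions about breakpoint-level precision
or alignment artefacts on real BAMs are outside what these tests show.

A practical scale effect worth knowing: the per-sample normalization factor
is computed from the genome-wide mean, so on a short simulated chromosome a
multi-kbp deletion measurably shifts its carriers' genome-wide mean and
leaks a small uniform offset into every window. On a real chromosome
(tens of Mbp) the effect is negligible; simulations here use ≥ 0.5 Mbp so
the offset stays well below one per-window standard error, and the
deletion-recovery tests read the *longest* significant run.

## Genotype QC

Markers are pruned on MAF < 0.05, call rate < 0.95 (samples first, at
0.95), and Hardy-Weinberg violation in controls. The HWE rule combines the
published thresholds conjunctively: exact-test p < 10⁻³ AND
Benjamini-Hochberg FDR < 0.2, both computed in controls only; an
`hwe_fdr_only` switch gives the FDR-only reading. The exact test is the
standard conditional test (probability of heterozygote counts as or less
probable than observed given the allele counts), implemented in log-gamma
form and verified against an exact-rational enumeration oracle for all
small tables.

Kinship is the allele-frequency-weighted GRM with pairwise-complete
handling of missing calls. Note the estimator's finite-sample property:
with sample-estimated frequencies the expected off-diagonal is −1/(n−1),
so "near zero" checks need n ≳ 100. MDS is classical scaling of
d²_ij = K_ii + K_jj − 2K_ij (the standard kinship-to-distance transform;
no alternative is claimed), with axis signs fixed deterministically and
outlier flagging at a configurable z (default 4) on the first two axes.

## Mixed-model association

The binary phenotype is analysed on the linear 0/1 scale (matching the
score-test-on-Gaussianized-residuals family of methods); a logistic mixed
model is out of scope. h² is profiled on a 0–0.99 grid (step 0.01) and
refined by golden-section search; β and σ² are profiled analytically in
the eigenbasis of 2K, making the fit deterministic and O(n³ + grid·n).
The per-marker score statistic uses the GLS projection P of the fitted
covariance; missing dosages are mean-imputed for the test only, and
monomorphic markers are reported with p = 1 and a flag rather than an
error.

Permutation significance permutes phenotype labels, which ignores the
kinship structure under the null — an approximation; the h² fitted on the
observed phenotype is reused across permutations (mean and residual
variance are refit per permutation) because full variance-component refits
per permutation cost ~100× more without materially changing the minima
distribution at these sizes. The 95% QQ band is the Beta(i, m−i+1)
order-statistic band, the standard construction for "empirical SNP
distribution confidence intervals".

The package's λ calibration claim is property-based: on sib-pair cohorts
with a heritable binarized liability, the mixed-model scan keeps
λ ∈ [0.9, 1.1] over 10,000 markers while the naive Armitage scan inflates
above 1.1. Cohort-level λ values from the original study depend on its
unpublished genotypes and are not reproduction targets.

## Locus definition and summaries

LD is composite genotype-correlation r² (phase-free); EM haplotype r² is a
possible extension, not implemented. The locus is the min–max positional
envelope of markers reaching the threshold on the anchor's chromosome —
intervening low-r² markers do not break it, which is consistent with the
published boundary coordinates. All coordinates are 1-based inclusive, so
span = end − start + 1 reproduces the printed 8875-bp and 3700-bp deletion
sizes and the 8.9/4.18-Mbp locus spans exactly; BED output converts to
0-based half-open on write only. Odds ratios are computed from allele
frequencies or count tables (two decimals), not from mixed-model
coefficients, so they are reproducible from printed MAFs.

## Fine-mapping filters

`prune_identical` requires all three high-coverage genotypes equal (raw
calls); variants with any missing call are retained with a flag. The
imputation filter is strictly two-step and order-fixed: markers with
allelic R² < 0.75 are dropped wholesale first, then surviving genotypes
with posterior < 0.8 are set missing. Merging two genotype sets resolves
(chrom, pos) duplicates by higher call rate (ties keep the primary set's
copy), harmonizes swapped ref/alt by flipping dosage, flags strand-ambiguous
(A/T, C/G) pairs and drops incompatible allele pairs with a report. The
functional-category prioritization of the original analysis needs external
annotation tracks; only a generic annotate-and-rank hook over user-supplied
interval tracks is provided.

## CNV scan and caller

Welch's unequal-variance t-test is the default per-window test ("a t-test"
is all the source method states); the pooled Student variant is a config
option. The Bonferroni denominator counts retained (non-excluded) windows.
The terminal partial window is kept and flagged. A caveat the test suite
encodes: if one depth group mixes heterozygous and homozygous deletion
carriers, its within-group variance explodes and Welch's test loses power —
the resequencing design this package emulates avoids that by construction
(heterozygous carriers at low coverage, the homozygote at high coverage).

The CNV caller is a transparent threshold-merge segmenter, not a mean-shift
reimplementation: consecutive windows below 0.75× (deletion) or above
1.25× (duplication) of the sample's genomic median are merged, with an
optional integer-bin GC median correction. It exists to produce calls
carrying the same downstream fields (p of mean-RD difference from the
genomic average, q0 fraction, span) so the published filter chain —
p < 0.001, span > 1000 bp, q0 ≤ 0, zero gap overlap — is exercised
verbatim; the filter chain and window scan, not the caller, are the
contribution re-implemented here. Single-window or zero-variance segments
get a Gaussian-tail p using the genome-wide window SD (a one-sample t is
undefined there); p-values are floored at the smallest positive float.

## Deletion genotyping and association

Copies of the intact chromosome follow the depth ratio with thresholds
0.25 and 0.75 (configurable); at ≥ 5X over an ~9-kbp deletion the Poisson
window noise gives ratio SDs around 0.03, so the bands are ~8 SDs wide —
hence the ≥ 99% recovery property. Concordance with a tagging SNP requires
the caller to declare which SNP allele tags the deletion; nothing is
inferred silently. Fisher's exact p is a direct hypergeometric summation
(two-sided, ties at 1 + 1e−12 relative tolerance) cross-checked against an
independent implementation in tests; the OR uses the Haldane–Anscombe 0.5
correction only when a cell is zero, with a Woolf logit CI. The published
deletion OR's exact CI method is unknown, so CI matching is not asserted
anywhere. The three-primer assay helper predicts product sizes by reference
arithmetic (no-deletion product = inner amplicon span; deletion product =
outer span − deletion span) and flags a forward primer inside the deletion
as unamplifiable; a zero-length deletion is not representable because
intervals are closed and non-empty.

## Pipeline

`run_pipeline` executes simulate → qc → gwas → locus → cnv_scan →
del_assoc from one pydantic-validated YAML config (unknown keys rejected),
with one derived seed per stochastic stage, and writes a manifest with
SHA-256 checksums of every output, so identical config + seed reproduces
identical bytes. The simulate stage puts the deletion in perfect LD with
the protective marker (carrier status = protective dosage) and picks
sequencing subsets mirroring the emulated design: heterozygous controls and
non-carrier cases at low coverage, a homozygous-protective control and two
non-carrier cases at high coverage.

## Problem sizes

Defaults were chosen so the full pipeline and all simulations run on a
laptop-class core: 500 markers / 107 samples for the end-to-end run,
10,000 markers / 120 samples for λ calibration, a 1-Mbp chromosome ×
20 samples × 100 replicates for deletion recovery, and 4 × 500-kbp null
replicates for window-scan type-I error. Larger sizes change none of the
qualitative results; they only tighten the Monte-Carlo intervals.

## Known limitations

- No logistic mixed model; effect sizes come from allele counts, not model
  coefficients.
- Permutations are not structure-preserving (see above).
- The caller is not a mean-shift segmenter and makes no claim of CNVnator
  parity beyond the downstream field contract.
- The depth model cannot exhibit alignment-driven artefacts (soft-clipped
  pileups, mapping-quality gradients), so q0-mask handling is exercised
  only through the simulated mask geometry.
- X-chromosome/sex-specific handling is absent; genotypic sex enters only
  through the provided phenotype column.
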