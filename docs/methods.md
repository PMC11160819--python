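# Methods

## Overview

pgskit computes polygenic scores (PGS) from scoring files against target
genotypes and places the raw scores on relative scales that are comparable
across genetic ancestry groups. The pipeline has five stages:

1. **Scoring-file ingestion** — parse and combine PGS scoring files into a
   single variant-by-score weight table.
2. **Variant matching** — resolve each score variant against the target's
   ref/alt alleles, handling allele-order swaps, strand flips,
   effect-allele-only records, palindromic sites and multi-allelic sites,
   with an auditable per-variant log.
3. **Scoring** — `SUM = Σ_j w_j · d_j` over kept variants, where `d_j` is
   the effect-allele dosage in [0, 2]; missing genotypes skip the variant
   and shrink that sample's denominator (`DENOM = 2 × variants used`).
4. **Ancestry estimation** — PCA of a labelled reference panel on the
   panel/target variant overlap; each target is projected into the PC
   space and assigned its *most similar* reference population.
5. **Normalization** — three relative scales per sample:
   `Z_MostSimilarPop` (empirical standardization against the most similar
   population's reference score distribution, plus a mid-rank percentile),
   `Z_norm1` (residual from an OLS regression of reference SUM on PCs,
   divided by the reference residual sd), and `Z_norm2` (the same residual
   divided by an ancestry-predicted sd from a second regression of squared
   residuals on PCs).

## Matching model

A score variant carries an effect allele (EA), optionally an other allele
(OA), and a weight. Against a co-located target variant with alleles
(ref, alt), classification tries, in order: EA=alt & OA=ref (`altref`),
EA=ref & OA=alt (`refalt`), then the same two after reverse-complementing
both score alleles (`altref_flip`, `refalt_flip`). Without an OA only
direct equality is accepted (`no_oa_alt`, `no_oa_ref`) — flipping a single
allele is unverifiable. A pair mapped onto itself (swapped) by reverse
complement (A/T, C/G) makes strand undecidable; such matches are flagged
ambiguous and excluded unless `keep_ambiguous` is set. Matches to variants
split from multi-allelic records are excluded unless `keep_multiallelic`.
Among surviving candidates at one position the best class wins (non-flipped
before flipped, OA-resolved before no-OA); exact ties keep the first target
in file order and log the rest as `duplicate_best_match`.

A score whose kept fraction falls below `min_overlap` (default 0.75) is
refused outright rather than silently computed on a subset: a partial score
misrepresents the published PGS. The default and the hard-stop policy are
this package's choices.

Indel alleles are matched by exact string only — no left-alignment or
normalization — on the assumption of harmonized inputs; likewise the
position index is exact (chrom, pos) with no fuzzy windows.

## Scoring choices

* Missing dosages are **skipped, never mean-imputed**: scoring files carry
  no allele frequencies, so imputation would be guesswork; the denominator
  records exactly what was used.
* Dominant/recessive effect types threshold the *oriented* dosage at 0.5
  and 1.5 respectively, which reduces to the usual "≥1 copy" / "2 copies"
  semantics on hard calls while still resolving fractional imputed dosages.
  How non-additive weights should interact with dosage uncertainty is an
  interpretation, flagged as such.
* Summation order is canonical — chromosomes in natural order, file order
  within a chromosome, per-chromosome subtotals added in chromosome order —
  so whole-file and split-per-chromosome runs are **bitwise identical**,
  not merely close.

## Ancestry model

Variant overlap between panel and target is keyed by position with allele
pairs reconciled up to orientation (ref/alt swap ⇒ target dosage reflected
to 2−d) and strand (reverse complement). Palindromic sites are excluded
from the PCA variant set unconditionally, independent of the matching
policy: a strand error here rotates the whole ancestry space, which is far
more damaging than losing one score variant.

The overlap is LD-pruned greedily (windows of 250 variants stepping by 25;
drop the later of any pair with r² > 0.1). Reference dosages are
standardized per variant by `(d − μ)/σ` with `μ` the mean dosage and
`σ = sqrt(2·(μ/2)(1−μ/2))` (the binomial scale at the panel allele
frequency); monomorphic variants are dropped. The PCA is the SVD of the
standardized matrix: loadings = right singular vectors, reference
coordinates = U·S, with the sign convention that each loading column's
largest-magnitude entry is positive (refits are bit-reproducible). K
defaults to 10 and must not exceed the numerical rank.

**Projection.** The naive projection `x·V` is biased toward the origin when
reference samples ≪ variants (PCA shrinkage). The default OADP projection
(online augmentation, decomposition, Procrustes) appends the standardized
sample row to the reference matrix, decomposes the augmented matrix
(directly — exact at these scales; the incremental online update is an
optimization, not a different algorithm), takes the top-K coordinates, and
maps them back through the Procrustes transform (rotation + isotropic
scale + translation) that best aligns the augmented reference coordinates
with the model's. Note that at truncated K the augmented subspace is
perturbed by the new row on the order of ‖row‖²/eigengap, so a sample
identical to a reference sample lands *near*, not exactly on, that sample's
coordinates; exact agreement holds at full rank.

**Assignment.** Most-similar population = smallest Mahalanobis distance to
each population's centroid in PC space, with per-population covariances
ridge-regularized by 1e-6·I; exact ties break to the lexicographically
first label and are logged. This rule is deterministic and parameter-light;
the assignment is reported as similarity, never as an ancestry label.

## Normalization model

Let `S` be a sample's raw SUM and `c` its PC coordinates.

* `Z_MostSimilarPop = (S − μ_pop)/σ_pop` with `μ_pop, σ_pop` (ddof=1) from
  the reference samples of the most similar population; the percentile uses
  the mid-rank convention (ties count half), which makes reference
  self-percentiles exactly uniform.
* Mean model: pooled OLS of reference SUM on `[1, PC1..PCK]` (all reference
  samples pooled, not population-weighted — a documented choice);
  `Z_norm1 = (S − ĉ·β)/σ_resid` with `σ_resid` the sd of reference
  residuals (guarded to ε when the score is fully explained by the PCs).
* Variance model: pooled OLS of squared residuals on the same design;
  `Z_norm2 = resid / sqrt(max(predicted variance, 0.01·σ_resid²))`. The
  linear variance model can go negative far from the reference cloud; the
  floor (1% of the residual variance) keeps the output finite, and floored
  predictions are logged. A log-link variance model would avoid the floor
  but is a larger modelling commitment than the data here justify.
* The regressions use the same K as the PCA.
* All three scales are exactly invariant under `S → k·S + c` (k > 0)
  applied to reference and targets alike.

The reference panel is **re-scored per run with exactly the kept-variant
set used for the targets** — a precomputed panel score would drift from the
target score whenever the match rate differs.

## Synthetic data

The generator follows the Balding–Nichols model: ancestral frequency
`p ~ Uniform(0.1, 0.9)` per variant; population frequency
`~ Beta(p(1−F)/F, (1−p)(1−F)/F)` so that `F ≈ F_ST`; dosages
`~ Binomial(2, p_pop)`. Admixed targets draw one allele from each of two
parent populations. Variants take positions 1..m round-robin across
chromosomes 1–22 with random non-palindromic ref/alt pairs (palindromic
sites only on request). A Weir–Cockerham estimator verifies the
calibration (F = 0.1 estimates land near 0.1; F → 0 estimates vanish).

What the generator does **not** emulate: linkage disequilibrium (all
variants are exchangeable draws — so LD pruning is exercised only against
structure-induced correlation), genotyping/imputation error, realistic
site-frequency spectra, relatedness, and phenotypes. Passing tests
demonstrate correctness of the pipeline's algebra and the normalization's
behaviour under controlled structure; they do not demonstrate robustness to
real-data artifacts such as imputation quality gradients between cohorts.

The hazard injector mutates a stated fraction of scoring-file variants per
hazard class (strand flip, allele swap, dropped other allele, palindromic
site, multi-allelic site, off-position) and returns the exact verdict the
matcher must reach for each, giving truth-table tests of the whole matching
policy. Ancestry-confounded scores for the normalization tests are built by
tilting the alt-oriented weights along a population frequency gradient
(`w_j += λ(f_{1j} − f_{3j})`); λ = 0.15 yields a raw-score separation of
several within-population sd at F = 0.1.

## Test sizing

Simulations in the test-suite are sized so each property is a genuine test
of the method rather than of sampling luck, while keeping the suite fast:

* matching/scoring oracle checks use 100 randomized ≤50-variant fixtures
  and 20×30 blocks (agreement is exact, so size only buys case coverage);
* shrinkage and assignment checks use 3 populations × 100 reference
  samples at 2000 variants (samples ≪ variants, the regime where shrinkage
  is visible);
* the normalization property uses 2000 reference and 2000 target samples
  per population at 500 variants: the per-population mean of an adjusted Z
  then carries a sampling error of ≈ √(2/2000) ≈ 0.03, making the ±0.1
  tolerance band a ~3σ test of method bias. (At 200 samples per
  population the same band is exceeded ~30% of the time by a perfectly
  calibrated method — a coin flip, not a test.) In this samples ≫ variants
  regime projection shrinkage is negligible, so the direct projection is
  used there.

## Numerical and degenerate-input policy

* Determinism: no randomness outside the seeded generator; PCA sign
  convention fixes the SVD gauge; gzip headers are pinned (no mtime or
  filename) and floats are formatted with `%.10g`, so identical runs are
  byte-identical.
* Missing reference dosages are mean-filled before standardization;
  missing target entries standardize to 0 (the reference mean).
* Degenerate guards: empty scoring files, duplicate variants, duplicate
  pgs_ids, overlapping chromosomes across files, sample-order mismatches,
  K > rank, singular regression designs, populations with < 3 samples, and
  zero-variance Procrustes problems all raise typed errors naming the
  offending input.

## Known limitations

* rsID-only scoring files are rejected (positional matching only); no
  liftover between genome builds.
* Indels must be exactly normalized already; no left-alignment.
* PLINK binary input is not implemented; VCF is the contractual format.
* The variance model for `Z_norm2` is linear in the PCs with a floor;
  extreme extrapolation far outside the reference cloud saturates at the
  floor rather than extrapolating variance.
* The reference panel must contain every population one wants scores
  compared against; admixed or unrepresented-ancestry samples are exactly
  the cases where `Z_norm1`/`Z_norm2` (label-free) are preferable to
  `Z_MostSimilarPop`.
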