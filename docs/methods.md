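# Methods

## Problem and model

Promoter-anchored chromatin interactions (PAIs) — functional links between
a gene promoter and a nearby regulatory region — are expensive to assay
directly at cohort scale. `paikit` predicts them from cis-mQTL summary
statistics: if the DNA methylation (DNAm) levels of two CpG sites within
2 Mb of each other are driven by the *same* causal variants, the two loci
are very likely in physical or functional contact.

The statistical engine is summary-data-based Mendelian randomisation (SMR)
with the HEIDI heterogeneity filter.

**SMR ratio test.** For exposure probe x (in a promoter), outcome probe y,
and instrument SNP z with per-allele effects b_zx, b_zy (SD units of DNAm):

    b_xy = b_zy / b_zx
    T_SMR = z_zx² z_zy² / (z_zx² + z_zy²),   z = b / se

T_SMR is referred to χ²(1) (two-sided Wald test). It is bounded by the
weaker of the two marginal chi-squares, so both associations must be strong.
`se_xy = |b_xy| / √T_SMR`, which is exactly Wald-consistent with the
reported p-value (we deliberately do not use a second-order delta
expansion).

**HEIDI.** A significant T_SMR can also arise from linkage: two distinct
causal variants in LD, one per probe. Under a single shared causal variant,
every instrument i estimates the same b_xy, so d_i = b_xy(i) − b_xy(top)
are jointly zero. Their first-order (delta-method) covariance is

    cov(b̂_xy(i), b̂_xy(j)) = b_xy(i) b_xy(j) r_ij ·
                             [1/(z_zx(i) z_zx(j)) + 1/(z_zy(i) z_zy(j))]

with r_ij the signed LD correlation from a reference panel, exposure and
outcome scans treated as independent (see "Sample overlap" below). The test
statistic T = Σ d_i²/V_ii follows a weighted sum of 1-df chi-squares whose
weights are the eigenvalues of the correlation matrix of d. Small p_HEIDI
(< 0.01 by default) rejects the single-shared-variant model, and the pair
is discarded as linkage.

**Instrument set.** The top instrument needs p < 5e-8. HEIDI instruments:
exposure p < 1.57e-3 (z² > 10), pairwise r² ≤ 0.9 with everything already
retained (greedy, significance-ranked), r² ≥ 0.05 with the top SNP (a
near-uncorrelated SNP carries no heterogeneity information), at most 20
SNPs including the top, minimum 3 — otherwise p_HEIDI is NA and the pair is
conservatively not a PAI (configurable).

## Numerical choices

* **Weighted-chi-square tail.** Default is the two-moment Satterthwaite
  match (scale·χ²_df with scale = Σλ²/Σλ, df = (Σλ)²/Σλ²); the exact Imhof
  inversion integral is available as `heidi_method="imhof"`. Measured
  against Imhof on LD-structured instances, Satterthwaite is exact when all
  eigenvalues are equal, has median relative error below 10% for
  p ∈ [1e-3, 0.5], but can deviate by up to a factor of ~5 in the far tail.
  Near the 0.01 decision threshold the deviation can reach tens of percent;
  verification runs should use Imhof (~10-100 ms per test vs ~0.1 ms).
* **Covariance flooring.** V is symmetrised and its eigenvalues floored at
  zero; components with V_ii ≈ 0 are dropped, and fewer than 2 surviving
  components yields NA. The covariance itself is a first-order expansion:
  its agreement with the Monte-Carlo covariance of d (3 MC SEs at 50,000
  draws) holds in the strong-instrument regime (z ≳ 20); at z ~ 5-10 the
  truncation error reaches several percent of the entries.
* **Ties.** Top-instrument ties on p break by larger |z|, then smaller
  position, then lexical SNP id. Promoter-promoter orientation: larger
  variance explained (q² = 2p(1−p)b², z-based fallback
  q² = z²/(z²+n−2) when the allele frequency is absent) is the exposure;
  ties by smaller top-instrument p, then smaller position; each pair is
  tested in exactly one orientation.
* **Boundaries.** Significance uses strict inequalities: p_SMR <
  alpha/n_tests with n_tests the number of pairs with a computed SMR
  p-value, p_HEIDI > cutoff. Coordinates: intervals are 0-based half-open
  (BED), point features 1-based; conversion happens only at query
  boundaries.

## Sample overlap

Exposure and outcome mQTL effects typically come from the same cohort. The
HEIDI covariance omits the resulting cross-covariance terms (they are set
to 0). The `simgen.null_overlap_experiment` reproduces the worst case:
both phenotypes measured in one cohort, residual phenotypic correlation
r_p ~ U(−0.5, 0.5), exposure heritability q² ~ U(0.03, 0.3), and *no*
genetic effect on the outcome. SMR p-values remain uniform (KS test and
the fraction below 0.05 are both checked in the acceptance suite), so the
omission does not inflate the test. The uniform r_p and q² ranges are
declared stand-ins for unpublished cohort-specific distributions, not
reproductions of them.

## Synthetic data

The generator reproduces the statistical structure the method assumes, not
human-genome realism:

* **Genotypes.** 2n haplotypes from a first-order Markov chain: site j
  copies site j−1 with probability ρ (default 0.8-0.9), otherwise draws a
  fresh allele with a frequency corrected to keep the marginal at its
  target MAF (uniform in [0.1, 0.5] by default). Haplotype LD decays as
  ρ^|i−j| in closed form, which makes the LD oracle checks exact; diploid
  counts inherit the correlation. This deliberately trades realistic
  human LD maps for analytic tractability.
* **Methylation.** Continuous, standardised to unit variance — the
  statistics operate on SD-unit summary data, so the bounded beta-value
  scale of array data matters only upstream of what is modelled here.
  Scenarios: pleiotropy (x = √q²·g + e, y = b_xy·x + e′, defaults
  q² = 0.1, b_xy = 0.5), linkage (independent causal SNPs at a chosen LD,
  no direct x→y effect) and the overlap null above.
* **Summary statistics.** Per-SNP simple OLS with n−2 residual df,
  matching what mQTL pipelines report.
* **Fixture bundle.** One 4 Mb chromosome, 2,000 SNPs, n = 2,000, 50
  probes: 10 promoter baits, 6 pleiotropic partners (true PAIs), 2 linkage
  partners, 2 overlap-null partners, 30 background probes, plus consistent
  promoter/TAD/loop/state/ChIP/eQTL/TPM annotations with signal planted at
  the pleiotropic pairs. A green end-to-end test establishes that the
  pipeline recovers planted pleiotropy and rejects planted linkage and
  overlap-null pairs *in this idealized world*; it says nothing about
  probe measurement error, cell-type heterogeneity, or realistic LD.

## Enrichment analyses

All enrichment tests compare an observed statistic on the predicted set
against `n_sets` (default 1,000) matched control sets resampled from the
universe actually tested in the scan, reporting fold = observed/null-mean
and empirical p = (r+1)/(R+1), displayed as "< 0.001" when no null value
reaches the observation at R = 1,000. Matching: pair distance in 20 equal
log10 bins over the universe range (empty bins widen to adjacent bins);
probe DNAm variance in deciles; gene-pair distance as for pairs. Controls
are drawn from tested probes/pairs/genes, not random genomic positions, so
the tests are conservative in the same way the underlying design is.
TAD overlap requires both probes inside one and the same TAD interval by
default (`mode="any"` relaxes this, since "mapped to the TAD regions" is
ambiguous); loop overlap requires the two probes in the two different
anchors (pad configurable, default 0); ChIP/eQTL site windows are 10 kb
total, centred. The loop-threshold sweep uses a 2×2 Fisher exact test on
probe-pair units (reported explicitly in the output). Gene expression
groups use median TPM across samples, inactive below 0.1, active genes in
quartiles. Each analysis derives its RNG sub-seed from the pipeline seed
and its own name, so adding analyses never perturbs existing results.

## Cross-tissue comparison

Replication is reported at the Bonferroni threshold alpha/n_available and
at nominal 0.05 (both requiring p_HEIDI > 0.01 in the replication tissue),
together with the sign-discordant replicated pairs. The threshold-free
r_b estimator corrects the naive Pearson correlation of effect estimates
for estimation-error variance:

    r_b = cov(b̂1, b̂2) / √[(var(b̂1) − mean(se1²)) (var(b̂2) − mean(se2²))]

with a leave-one-out jackknife over pairs for its SE, clamping to [−1, 1]
with a flag. Error covariance between tissues is set to 0 (independent
cohorts); a config slot accepts a nonzero error correlation. When the
corrected variance is non-positive (effects nearly identical or SEs larger
than the effect spread) r_b is NA with a diagnostic rather than a number.

## Known limitations

* The HEIDI covariance and tail approximations degrade for weak
  instruments and extreme eigenvalue spread (quantified above).
* The top-instrument choice carries a small winner's-curse deflation of
  b̂_xy; measured at q² = 0.05, n = 2,000, m = 100 candidate SNPs it is
  below 1% and statistically indistinguishable from zero at 4,000
  replicates.
* Interval queries, the Markov LD model and the fixture bundle target
  desk-scale instances (10²-10⁴ features); none of the code paths are
  tuned for genome-scale inputs.
* Trans (inter-chromosomal) pairs, multi-SNP SMR, COJO conditioning and
  loop calling are out of scope; eQTL lists are consumed already clumped.
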