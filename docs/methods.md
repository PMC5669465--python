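# Methods

## Statistics implemented

**Minor-allele content (MAC).**  For a designated reference group
(controls only, or the combined cohort), each biallelic SNP's minor allele
is the allele with frequency < 0.5 over that group's non-missing
genotypes; a tie at exactly 0.5 is broken toward the alphabetically first
allele and flagged.  SNPs with reference MAF in [0.4, 0.5] are excluded
from MAC scoring because their minor-allele assignment is dominated by
sampling noise.  An individual's MAC is the sum of minor-allele copies
(het = 1, hom = 2) over eligible SNPs divided by the number of those SNPs
actually genotyped in that individual, so MAC ∈ [0, 2] and missingness
does not bias the score downward.  Copies rather than carrier status are
counted; this matches the hom/het distinction in the risk score and makes
MAC an average minor-allele dosage.  Group means are compared with
Welch's unequal-variance t-test, two-tailed.

**Known anticonservatism of the in-sample MAC test.**  Defining minor
alleles and the MAF < 0.4 eligibility cut on the *same controls* that
enter the t-test makes the null distribution slightly case-shifted: SNPs
near the 0.4 boundary enter the score preferentially when their control
frequency fluctuates low, which depresses control MAC relative to case
MAC.  The package's test suite measures this directly: with minor-allele
tables taken from the generative truth the test is exactly calibrated
(≈5% rejections at α = 0.05), while with in-sample tables on cohorts of
500 cases/500 controls × 2,000 SNPs the null rejection rate is ≈9–10%.
Both the conditioning band and the conditional shift scale as
1/√(n_controls), so the effect shrinks quickly with reference-group size,
but analysts should treat borderline MAC p-values from small control
groups with caution.  This is a property of the statistic's definition,
not of this implementation.

**Association and weights.**  Per-SNP additive logistic regression
(status ~ intercept + minor-allele dosage) on the training cohort, with
the minor allele defined on the *combined* training cohort so that the
reported β is the log-odds per minor-allele copy.  The numerical core is
a Newton–Raphson/IRLS fit with step-halving (log-likelihood is
non-decreasing by construction); Wald z and two-tailed asymptotic
p-values.  Quasi-separation (|coefficient| > 15) and monomorphic SNPs are
flagged `converged=False` and excluded from risk models rather than
penalized — at the sample sizes this pipeline targets, separated SNPs are
almost always artifacts.  The per-SNP scan is a vectorized closed-form
2×2 Newton solver, chunked over SNPs; the general IRLS routine serves the
multivariate covariate model and Nagelkerke R².

**Risk score.**  GRS = Σ β over model SNPs homozygous for the coded minor
allele + 0.5·Σ β over heterozygous SNPs (equivalently half the β-weighted
minor-allele dosage).  β keeps its sign — protective minor alleles
subtract.  Missing genotypes contribute 0 (non-carrier), a deliberate
literal reading that diverges from the mean-dosage imputation common in
PRS tools; model SNPs absent from a scored cohort contribute nothing and
the overlap count is reported, so transfer to a partially overlapping
array is well-defined.

**LD pruning.**  r² is the squared Pearson correlation of dosage vectors
over pairwise-complete observations (composite LD; no phasing — phase is
not in the data model and a correlation screen is all pruning needs).
Scanning SNPs in (chromosome, position) order, each still-kept pair
within a 200,000-bp window with r² above threshold loses one member by a
seeded fair coin, until no violating kept pair remains; a brute-force
verifier re-checks the invariant in tests.  Pair statistics are computed
as chunked gram-matrix products, which is exactly the per-pair
pairwise-deletion formula, just batched.

**Evaluation.**  AUC is the Mann–Whitney statistic (ties count ½) with a
DeLong structural-components 95% CI.  TPR at 100% specificity is the
fraction of cases *strictly* above the best control, with a Wilson
binomial CI — the CI method is this package's choice.  Nagelkerke
R² = [1 − (L0/L1)^(2/n)] / [1 − L0^(2/n)] from the intercept-only and
score logistic likelihoods.

**Model grid and selection.**  35 P thresholds (1e-33 … 1) × 6 LD levels;
the five r² values are joined by a "no pruning" level, the only reading
that makes the 35 × 6 = 210 count come out.  External validation trains
everything (MA tables, betas, pruning) on the training cohort once and
only ever *scores* the validation cohort; a poisoning test asserts that
validation labels cannot reach the training fits.  Internal 5-fold CV is
stratified by status and refits everything per fold — the only leak-free
reading.  "Best in both" is operationalized as the minimal sum of the
external-AUC rank and the internal-mean-AUC rank, ties broken toward
fewer SNPs and then the larger threshold.  The winning model is rebuilt
with flip SNPs (control-defined minor ≠ combined-defined minor) removed.
A threshold of 1 is treated as vacuous and admits every converged SNP,
including the few whose two-sided p rounds to exactly 1.0.

## Synthetic cohorts

The generator emulates what the statistics above actually touch, nothing
more.  Genotypes come from a Gaussian-copula haplotype model: per
haplotype a latent standard normal with exchangeable correlation `ld_rho`
inside each fixed-size block, thresholded at the MAF quantile; two
haplotypes sum to dosage.  This gives direct control of the MAF spectrum
and within-block genotype r² without coalescent machinery.  Blocks are
laid out on chromosomes 1–22 with 5-kb SNP spacing inside blocks and 1-Mb
gaps between blocks, so the 200-kb pruning window aligns with block
structure.  Disease status follows a logistic model on the *centered*
genetic score, `logit P(case) = intercept + Σ β_j (g_j − 2 maf_j) + Σ γ_k
x_k`, so `expit(intercept)` is the approximate prevalence regardless of
effect sizes; case-control panels are then assembled by rejection
sampling until both quotas fill, mirroring ascertained designs.  MAC
enrichment is induced by `p_minor_risk`, the probability that a causal
effect's risk allele is the minor allele (default 0.8).  An optional
two-subpopulation mode draws the minority's allele frequencies from a
Balding–Nichols Beta around the base MAF (`fst` parameter) for
PCA-outlier testing.  One integer seed derives all streams (structure,
genotypes, missingness, splits) at fixed offsets; identical configs are
bit-reproducible.

Defaults, chosen once as the study conditions: MAF ~ Uniform(0.01, 0.5);
blocks of 20 SNPs at latent ρ = 0.9 (realized within-block genotype r²
has median ≈ 0.34 with tails on both sides of every pruning threshold);
intercept −2.2 (≈10% prevalence); effect magnitudes |N(0.05, 0.02)| for
the generic small-effect default.  Effect-size laws are tuple-coded;
besides uniform/normal/constant there is a point-normal
`("mixnormal", p_large, sd_small, sd_large)` mixing a polygenic
background with a minority of strong loci — the architecture (akin to a
handful of GWAS-grade loci over a polygenic tail) under which a
marginal-beta risk score can approach the true-effect oracle at
desk-scale sample sizes.  What the generator does *not* model: realistic
human LD maps and allele-frequency spectra, genotyping error,
relatedness, imputation uncertainty.  Passing tests therefore demonstrate
the pipeline's statistical machinery, not performance on real arrays.

## The packaged demonstration cohort

`macrisk.pipeline.demo_config(seed)`: 4,000 cases / 4,000 controls, 5,000
SNPs (MAF 0.05–0.5), 300 causal with β ~ mixnormal(0.12, 0.05, 1.0),
p_minor_risk 0.8, latent ρ 0.3, 2% missingness.  Low LD is deliberate
here: under strong LD, single-SNP marginal betas double-count block
effects and the summed score drifts away from the oracle — the LD-heavy
regime is exercised by the MAC and pruning tests instead.  The sizes are
chosen so the whole 210-model grid with internal 5-fold CV runs in a few
minutes on one CPU.  A fundamental feature of this design, measured
during development and reproduced by the acceptance script: with many
equal small effects, marginalizing the logistic model over the polygenic
background attenuates every per-SNP β by ≈ 1/√(1 + 0.346 σ_g²), which
caps per-SNP power and keeps any marginal-weight score strictly below the
oracle; concentrated architectures close that gap.

## Numerical choices and degenerate inputs

Monomorphic SNPs: HWE returns (χ² = 0, p = 1); association flags them
unconverged; r² against them is 0 (flagged).  Samples with zero usable
SNPs are dropped from MAC with a warning.  Half-missing PLINK genotypes
("A 0") are treated as fully missing.  Identical degenerate score vectors
give t = 0, p = 1.  PCA standardizes mean-imputed dosage columns and uses
a seeded randomized SVD; PC signs are fixed by making each component's
largest-magnitude loading positive.  QC reason attribution is
first-failing in the order non-autosomal → missingness → MAF → HWE
(cases, then controls); the accounting identity `n_in = n_out + removed`
is asserted on every run.  The `.ped` reader defines `allele_b` as the
second allele observed scanning the file; since the format does not
record orientation, a rewritten file can read back with flipped
orientation at SNPs whose first non-missing genotype is homozygous for
`allele_b` — the information is identical, and round-trip tests compare
after alignment.

## Limitations

Single-threaded; dense int8 genotype matrix in memory (a 100K-sample
biobank array would need a different backend).  No relatedness/IBD QC, no
sex chromosomes, no imputation dosages, no covariates in per-SNP fits.
The flip-SNP removal step can lower external AUC when near-0.5-MAF SNPs
carry genuine signal, as happens in the demonstration cohort — the
package reports both the pre-drop cell metrics and the final model's
evaluation so the effect is visible.
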