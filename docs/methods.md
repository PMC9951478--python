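# Methods

`tqtlkit` implements a complete desk-scale pipeline for mapping
cis-acting transcriptomic QTLs (eQTLs on gene expression, sQTLs on
intron junction proportions) in a multi-population cohort, fine-mapping
them into credible sets, and scanning the mapped loci for signatures of
positive selection. This note records the models, the conventions and
numerical choices behind each stage, and what the synthetic-data
generator does and does not emulate.

## Synthetic data

The generator produces a cohort with known ground truth so every stage
of the pipeline can be validated end to end.

**Genotypes.** Populations are differentiated under the Balding–Nichols
model: for a variant with ancestral frequency `p` (uniform on
(0.05, 0.95) by default) and population drift parameter `F`, the
population frequency is drawn `Beta(p(1-F)/F, (1-p)(1-F)/F)` (equal to
`p` when `F = 0`), and diploid dosages are `Binomial(2, p_pop)`. This
model was chosen because its expected pairwise Hudson F_ST is governed
directly by `F`, giving the downstream selection statistics a known
target. Defaults are 3 populations of 54 diploids (162 samples, the
size of a small whole-blood cohort) with `F = 0.05` per population.
Variants sit at a fixed 1 kb spacing on a single synthetic chromosome,
so a 100 kb cis window always holds about 200 variants. Admixed
individuals, realistic LD blocks from recombination, and sequence-level
detail are deliberately not simulated; passing tests therefore speak to
the statistical machinery, not to robustness against fine-scale LD or
admixture structure in real cohorts.

**Expression.** Each gene receives a TSS on the chromosome; a fraction
`frac_causal` (default 0.3) of genes get exactly one causal common
(pooled MAF > 0.05) variant inside their cis window, with per-allele
effect drawn `N(0, effect_size_sd)` (default SD 0.5 on the scale of the
normalized phenotype; the source cohort reports no effect-size
distribution, so this is an exposed placeholder). The phenotype is
effect x dosage + covariate contributions + `N(0, noise_sd)`. A Poisson
read-count layer (counts ~ Poisson(50 e^z) with z the standardized
phenotype) and a proportional TPM layer exist solely to exercise the
expression filters.

**Splicing.** Introns come in clusters (default 3 junctions per
cluster). Per sample, the cluster total is Poisson (mean 150; no
overdispersion by default, Dirichlet-multinomial behind
`splicing_overdispersion`) and junction counts are multinomial around
Dirichlet-drawn baseline proportions. For a causal cluster, the first
junction's proportion shifts on the logit scale by effect x dosage. The
phenotype is JPC — junction count over cluster total — which sums to 1
within a cluster, reproducing the compositional structure of real
junction data (a causal shift in one junction induces opposite-signed
associations in its siblings).

**Covariates.** A binary sex analogue, a continuous age analogue, and
`latent_factors` standard-normal latent factors with genome-wide
loadings; these stand in for measured technical/biological covariates
and for the latent expression heterogeneity that hidden-factor
inference is meant to absorb. Cell-type composition is not simulated.

Every operation draws from its own `numpy` Generator seeded by a fixed
stream tag plus the config seed, so a config reproduces its outputs
byte-for-byte regardless of call order.

## Filtering and normalization

Expression features are kept when they have more than 5 reads in at
least 20 individuals and mean TPM strictly above 0.1; introns when at
most 5 individuals have zero reads, within clusters having at least 20
reads in at least 100 individuals and fewer than 10 zero-read
individuals. Filters run before normalization.

Normalization is the two-stage quantile procedure used by the large
reference expression atlases: stage 1 maps every sample's distribution
onto the across-sample mean order statistics (ties receive the mean of
the reference values their positions span); stage 2 rank-transforms
each feature to `Phi^-1((r - 0.5)/n)` with average ranks for ties (Blom
offsets `(r - 3/8)/(n + 1/4)` behind a flag — neither offset is
canonical, and the choice moves nothing downstream since only ranks
enter the scan). A feature constant in the raw input carries no rank
information and is forced to all-zero output and flagged; note that
stage 1 would otherwise break the constancy through the per-sample
maps. With fewer features than samples, stage 1 introduces heavy ties
inside features (each feature's row takes values from only
`n_features` distinct reference values), so the "every feature is a
permutation of one quantile vector" property holds exactly only on
tie-free data; at realistic feature counts the effect is negligible.

Hidden expression factors are the top principal components of the
feature-centered phenotype matrix, sign-fixed so the largest-magnitude
loading is positive. This is a deliberate substitution for a
variational latent-factor model: for this pipeline the factors only
need to absorb broad expression heterogeneity, and the selection rule —
scan at each k on a grid and keep the k maximizing the number of
FDR-significant features, ties to the smallest k — is preserved, which
is what actually matters for discovery counts.

## Cis-QTL scan and hierarchical FDR

The scan tests each feature against every variant with pooled MAF
strictly above 0.05 within 100 kb of the gene TSS (distance to the
intron interval for sQTLs, zero inside it). Missing dosages are
mean-imputed inside the scan only; variants constant after imputation
are skipped.

*OLS:* phenotype on intercept + covariates + dosage, two-sided t test
(Wald) on the dosage coefficient. Implemented by residualizing
phenotype and dosages on the covariate design once (QR projection) —
algebraically identical to the full regression, including the
`n - p_cov - 2` degrees of freedom, and verified against a
normal-equations oracle at 1e-8.

*LMM:* a single-variance-component model `y ~ N(Xb, sigma_g^2 K +
sigma_e^2 I)` with the GRM `K = XX'/M` over standardized dosages
(population-variance standardization, so the diagonal mean is exactly
1). The model is solved in the GRM eigenbasis; the variance ratio
`sigma_g^2/sigma_e^2` is estimated once per feature by bounded scalar
REML on the covariates-only model, then each variant is tested by
weighted least squares at that ratio. This one-ratio-per-feature
shortcut is the standard mixed-model speedup; exact per-variant REML is
available behind `exact_per_variant_reml`. With `K = I` the weights are
constant and the LMM reduces to OLS exactly. Which test statistic the
original mixed-model tool used is not documented; the Wald t test is
adopted for both models.

Multiple testing is hierarchical Benjamini–Hochberg: BH within each
feature over its tested variants gives single-corrected `P'`; BH across
features on the per-feature minimum `P'` gives double-corrected `P''`;
features with `P'' < 0.05` are significant. The genome-wide SNP
threshold is the minimum `P'` of the significant feature with the
largest `P''`, and variants with `P'` **at or below** it are flagged —
the inclusive comparison (rather than strictly below) guarantees the
borderline feature's own lead variant is flagged, so every significant
feature has at least one significant variant.

Conditional analysis residualizes each feature's normalized phenotype
on intercept + covariates + its conditioning dosages (absent variants
dropped with a log entry; variants collinear with the covariates
dropped with a warning) and re-runs the identical scan; a feature is
*independent* if any variant attains `P'` at or below the original SNP
threshold, else *shared*. An empty conditioning set reproduces the
unconditioned scan exactly (the residualization is idempotent with the
scan's own covariate projection).

## Fine-mapping

Under a single-causal-variant assumption, each variant's approximate
Bayes factor is `log ABF = (log(1 - r) + z^2 r)/2` with `z = beta/se`,
`V = se^2`, `r = W/(V + W)`. When only a p-value is available, `|z|`
is recovered from the two-sided p (capped at 40 where p underflows)
and `V ~= 1/(2 n f (1-f))`; the sign never enters. The prior effect
variance defaults to `W = 0.15^2` — the conventional prior SD on a
unit-variance phenotype, appropriate because the scan phenotype is
standard-normal by construction after stage-2 normalization; the source
analysis does not state its prior, so this is a documented assumption,
configurable via `prior_sd`.

Posteriors are `PP_n = ABF_n / sum_p ABF_p` (computed via logsumexp),
and the 90% credible set is the minimal PP-descending prefix whose
cumulative mass strictly exceeds 0.9 (ties broken by smaller p, then
variant id; the strict inequality is guarded by a 1e-12 cumulative-sum
tolerance so that, e.g., ten variants at PP = 0.1 yield a set of ten).
Credible-set overlap between two analyses is non-empty variant-id
intersection, optionally after restricting each set to variants with
PP at or above a floor (0.1 reproduces a "greater than 10% causal
probability" comparison). Multi-causal fine-mapping and colocalization
posteriors are out of scope.

## Population-genetic statistics

Per-variant Hudson F_ST uses sample frequencies and allele counts
(`n = 2 x` non-missing diploids — the estimator's `n` is not defined in
the source, and this is the natural choice for diploid data):
`num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`,
`den = p1(1-p2) + p2(1-p1)`; set-level values are the ratio of averages
`sum(num)/sum(den)`. Per-variant values may be negative and are kept
for the d-statistic and enrichment work, but are clamped at zero inside
the PBS branch length `T = -log(1 - F_ST)` (a negative F_ST would make
the log argument exceed 1 and flip the branch-length semantics).
`PBS_focal = (T(focal,ref1) + T(focal,ref2) - T(ref1,ref2))/2`, with
negative PBS preserved.

The polarized d-statistic for focal population i is
`d_i = |sum_{j != i} s_j (F_ij - E[F_ij])/sd[F_ij]|` with `s_j = +1`
when `p_i >= p_j`, else `-1`; `E` and `sd` are computed once
genome-wide per pair over all variants with defined F_ST. The
polarization prevents variants at intermediate focal frequency but
differentiated among the other populations from scoring as focal
outliers (the two standardized terms cancel instead of adding).

LD is the squared Pearson correlation of dosages against a lead
variant within a window, computed on one population's samples and
restricted to variants polymorphic there.

## Selection scans

A feature's fine-mapping posteriors convert per-SNP statistics into one
locus score, `sum_p PP_p stat_p`, applied to F_ST, d, and PBS; missing
statistics are dropped with posterior renormalization, and the score is
always bounded by the locus's min and max statistic. The
background-selection control permutes the statistic across the locus's
variants (default 10,000 draws) against the fixed posterior vector;
empirical p-values use the add-one convention
`(1 + #{null >= obs})/(B + 1)` so they are never zero (the source does
not specify a convention). Exhaustive enumeration over all `n!`
permutations is available for loci of up to 8 variants and is used to
validate the sampler.

Global candidates need a weighted F_ST above the 99th percentile of
genome-wide per-SNP F_ST *and* permutation p below 0.01.
Population-specific candidates need weighted d and weighted PBS both
above the 99.5th percentiles of their genome-wide SNP distributions;
whether those calls also required a permutation p is not documented in
the source, so the permutation is optional there. Percentiles are
always computed from the supplied genome-wide vectors — the fixed
outlier constant reported for the original cohort (F_ST > 0.36) is a
property of that dataset, not of the method.

The F_ST-outlier enrichment test takes each lead SNP's maximum F_ST
over its LD set (r^2 > 0.8 companions, the lead itself included — the
source leaves inclusion unstated) and compares the outlier fraction
among leads with a matched null: every lead is replaced by a random
background SNP from the same MAF bin (width 0.05) and LD-set-size bin
(edges {0}, {1,2}, (2,5], (5,10], (10,20], (20,50], >50), drawn without
replacement within a replicate, leads excluded from the pool, empty
bins falling back to the nearest non-empty bin with a logged warning.
Annotation enrichment works the same way with matching on MAF and TSS
distance (decile bins over the pooled distances) and per-category score
`log((#QTL + 1)/(#background + 1))`; the pseudocount keeps the ratio
defined at zero counts.

## Replication statistics

`pi1 = 1 - pi0` with `pi0(lambda) = #{p > lambda}/(m(1 - lambda))` on
the grid 0.05–0.95 (step 0.05); the default "smoother" method fits a
cubic smoothing spline to `pi0(lambda)` and reads it at the largest
lambda, the "fixed" method reads `pi0(0.5)`; estimates are clipped to
[0, 1]. The exact binomial test is two-sided by the minimum-likelihood
rule (the sidedness is not stated in the source, but two-sided
reproduces its printed p-value). The one-sided two-sample KS test
reports the directed sup-difference of empirical CDFs with the
asymptotic tail `p = exp(-2 D^2 mn/(m+n))`; a label-permutation p is
available behind a flag for small samples. Effect-size concordance
joins two cohorts' records on (feature, variant), flips the sign of
effects reported on swapped ref/alt alleles, drops irreconcilable
allele pairs with a log entry, and reports Pearson correlation and
least-squares slope per replication class.

## Validation scale and reproducibility

The test suite validates at desk scale: FDR calibration on 50
global-null replicates of 300 features x 162 samples (about 200 cis
variants per feature), credible-set coverage on 200 single-causal
genes, pi1 recovery at m = 20,000, and permutation/enrichment
calibration over 200 loci and 50 null experiments — sizes chosen so the
whole suite runs in a few minutes on one CPU while keeping Monte-Carlo
error well inside the asserted tolerances. The cohort-level results of
the study this design mirrors (its eGene count, its replication pi1,
its candidate gene lists) depend on controlled-access human data and
external cohorts and are not reproduced here; what the suite
establishes is that each statistic is computed correctly and that the
inferential machinery is calibrated under its own assumptions.

Known limitations: single-causal-variant fine-mapping; no admixture or
realistic recombination in the generator; principal components in
place of a variational factor model; the pi0 smoother uses
`scipy`'s default spline smoothing rather than the df=3 convention of
the R implementation (both are "default smoothing" choices, and the
recovery tests bound the difference); KS p-values are asymptotic and
anti-conservative below roughly 50 observations per group.
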