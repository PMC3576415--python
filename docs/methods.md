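# Methods

This note records the models the package implements, the numerical and
design choices behind them, what the synthetic cohorts do and do not
emulate, and known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing model (DMH intensities)

A biological sample is hybridised to two replicate chips; raw probe
intensities are averaged **on the intensity scale** across the two
replicates before any log transform (the plain reading of
replicate-then-score processing; averaging after log2 would change
scores by the log of the replicate ratio). The methylation score of a
probe set on a chip is

    score = median(log2 probe intensities) − median(log2 control intensities),

which is invariant to any chip-wide multiplicative intensity factor —
this is what makes scores comparable across chips. Calibration maps
each probe set's score affinely so the 0%-methylated reference chip
scores 0 and the 100% chip scores 1. Calibration is **per probe set**
(the reference chips provide a per-feature anchor); a probe set whose
two anchors coincide is uncalibratable and dropped with a warning.
Calibrated scores may legitimately fall outside [0, 1].

Quantile normalisation maps every sample onto the across-sample mean of
sorted score vectors (the standard target); ties within a sample get
the mean of the reference quantiles they span, preserving within-sample
rank order.

Probe sets whose probes overlap common variants are excluded to avoid
allele-specific hybridisation artefacts: a probe's genomic footprint is
`[pos, pos + probe_length − 1]` with `probe_length = 50 bp` by default
(array manifests give probe start coordinates but not always lengths),
and a probe set is excluded iff any reference-panel SNP with MAF
strictly above 0.05 falls inside any footprint. Coordinates are 1-based
inclusive internally; BED I/O converts to/from 0-based half-open.

The bimodality QC statistic is a 2-vs-1-component Gaussian-mixture
likelihood ratio with a parametric-bootstrap p-value (50 bootstrap
draws by default). A dip-statistic test would serve the same role; the
mixture LRT was chosen because it needs only scikit-learn and detects
the hypo/hyper two-mode structure directly. QC is advisory and never
gates the pipeline.

## Primary cis-meQTL scan

For each probe set, SNPs with position in the closed interval
`[start − 500 kb, end + 500 kb]` on the same chromosome are tested with
OLS of methylation score on allelic dosage plus covariates (age, sex,
MetSyn), after the effective-minor-allele-count filter
`2·MAF·info·n > 5` (MAF = folded mean dosage / 2; `info` the
imputation quality). The scan uses the Frisch–Waugh–Lovell partialled
form — methylation and dosages residualised against the covariate
block once, then per-pair slopes from scalar products — which is
algebraically identical to the full per-pair OLS (verified against
both a normal-equations oracle and statsmodels in the tests) and makes
10⁵-test scans take seconds. Residual degrees of freedom are
`n − columns` including the intercept, so the default primary model has
38 − 5 = 33 df; p-values are two-sided Student-t tails. SNPs that are
constant (or collinear with covariates) within the analysed samples are
dropped from the scan with a count. With missing dosages the scan
falls back to per-pair OLS with listwise deletion and reports per-test
n.

Multiple testing uses Storey q-values pooled over **all** probe–SNP
tests (a per-probe switch exists): π₀ is estimated on the λ-grid
0.05–0.90 (step 0.05) by a cubic smoothing spline extrapolated to
λ = 1 and clipped to (0, 1]; for fewer than 100 tests the smoother is
unreliable and π₀ = 1 is used. q-values are the usual running minimum
of π₀·m·p/rank. The lead SNP per probe set is the smallest-p SNP with
ties broken by smaller SNP-to-probe-set distance, then lower position
(the tie-break is this package's own convention). Distance is measured
to the nearest probe-set boundary and is 0 inside the interval.

## Phenotype association

Each phenotype has a fixed adjustment set: MetSyn→{age, sex},
BMI→{age, sex}, age→{BMI, sex}, sex→{BMI, age}; the sex scan drops X/Y
probe sets before testing. The QQ confidence band permutes the sample
labels of the methylation matrix jointly across probes (preserving
inter-probe correlation), retains the sorted −log10 p curve per
permutation, and reports pointwise 2.5/97.5 percentiles. With B
permutations the band endpoints are order statistics, so per-quantile
coverage is slightly below the nominal 95% (≈94% at B = 500), and the
sorted quantiles of any single curve co-move — whole curves can sit
largely outside a pointwise band; the tests therefore check coverage
averaged over replicates. Variance shrinkage of a moderated-t
framework is deliberately not reproduced: plain OLS t is used, which
matters little for globally null phenotype scans.

## Replication in the twin cohort

A primary hit is matchable if a target-array CpG lies within 1 kb
(closed) of the probe-set interval; the nearest such CpG is taken. A
pair is testable if the lead SNP is genotyped in the replication panel
or a proxy with r² > 0.8 (squared Pearson correlation of dosages — the
composite-LD convention) exists; LD is computed from the reference
dosages, or from samples shared between panels for
replication-only SNPs. Allele harmonisation matches allele labels with
strand-flip resolution; strand-ambiguous A/T and C/G SNPs are resolved
by frequency matching (|ΔMAF| < 0.1) or flagged untestable.

The replication effect is the SNP fixed effect of a linear mixed model:

    beta-value ~ age + batch + BSC concentration + BSC efficiency
                 + dosage + (1 | family) + (1 | MZ pair) + ε

fitted by **maximum likelihood** (not REML). Zygosity enters as an
extra variance component shared by monozygotic pairs — the reading of
"family and zygosity random effects" adopted here; a zygosity-as-fixed
switch could be added but the variance-component form nests the DZ/MZ
covariance structure naturally. Because family blocks have at most two
members, the marginal covariance is block diagonal with closed-form
2×2 inverses; the likelihood is profiled over the residual variance
and optimised over the two variance *ratios* (L-BFGS-B, two starts,
ratios bounded at 0), making each fit sub-10 ms at n = 181. The fitter
is cross-checked against statsmodels MixedLM (ML) in the tests, and
degenerates exactly to OLS when the random effects vanish
(singleton families). The SNP is tested with −2 log(likelihood ratio)
against χ²(1) without boundary correction, as is conventional for a
fixed-effect test. Directional replication uses the one-sided Gaussian
tail of beta/se in the primary direction (erfc-based, no 1−CDF
cancellation), and the replication rate is tested with an exact
binomial upper tail (rational arithmetic for n ≤ 1000). The
conditional analysis refits the mixed model with both SNPs and tests
each conditional on the other; r² = 1 pairs raise a collinearity
error.

## Expression integration

A probe set is matched to the transcript whose strand-resolved TSS
(gene start on +, gene end on −) is closest to the probe-set boundary,
ties to the lower TSS. Methylation→expression and dosage→expression
models are plain covariate-adjusted OLS on the sample intersection of
the assays (no imputation of the unprofiled samples); q-values are
computed within each run (full probe list and hit subset separately),
so the two runs get their own corrections.

## Enrichment

The GWAS enrichment statistic is the sum over test SNPs of the rank of
their GWAS p-value within the annotated pool (small p ⇒ small rank;
invariant to monotone transforms of p). Each permutation draws, per
test SNP, one SNP matched on MAF (±0.05), distance to nearest gene
(±500 kb) and recombination rate (±1 cM/Mb), without replacement
within a permutation; a SNP with an empty matched pool has its
tolerances doubled until the pool is non-empty (unbounded as a last
resort) with a logged warning. Enrichment is one-sided:
empirical p = (1 + #{permuted ≤ observed}) / (B + 1), so p ≥ 1/(B+1)
by construction. "Distance to genes" is measured to the nearest
gene-body boundary in the annotation table supplied by the caller.
GO over-representation is a per-term hypergeometric upper tail over
the gene universe with Storey-FDR across terms; external
gene-set-enrichment and protein–network analyses are out of scope and
served by export files.

## Synthetic cohorts

The generator exists so every stage is testable without study data.
Genotypes: per-SNP MAF ~ Uniform(maf_range); two latent haplotype
Gaussians per sample follow a sliding AR copula with neighbour
correlation exp(−d/ld_decay_bp); thresholding at the MAF quantile
gives 0/1 alleles summing to dosages, so LD decays smoothly with
distance without modelling recombination. Info scores ~ Uniform(0.3, 1].
Methylation baselines are bimodal (hypo ≈ 0.15 / hyper ≈ 0.85, 55%
hypermethylated) on the calibrated score scale; planted cis effects
enter as beta × dosage on that latent scale; residual noise sd
defaults to 0.1 score units. DMH intensities are back-generated from
the latent scores through per-probe-set raw-score anchors
(0% ≈ −0.2, span ≈ 1.6) and multiplicative log-normal probe noise, so
preprocessing is exercised end to end; both replicate chips of a
sample share a batch, making replicates bit-identical at zero noise.
The twin cohort has 2×90 + 1 = 181 members (one unpaired individual is
deliberate, keeping group-handling code honest about odd cohorts); the
MZ/DZ split is a parameter (default 0.5) since it is not derivable
from the design; latent logit-scale scores add fixed covariate
effects, family intercepts (sd 0.3), MZ-extra intercepts (sd 0.2), the
planted SNP effect and residual noise, then squash through the
logistic to beta values in [0, 1]. Expression links are linear with
negative slope and TSS placed just outside the linked probe set.

What the generator does **not** emulate: realistic haplotype structure
or recombination hotspots, probe-sequence effects, bisulfite-conversion
chemistry, cell-type heterogeneity, and batch structure beyond additive
offsets. Passing tests therefore demonstrate the statistical machinery
(calibration of tests, FDR control, parameter recovery, power under
the stated noise model), not robustness to the artefact structure of
real arrays.

Determinism: every stochastic stage derives its generator from the
config seed plus a stage-specific offset; a fixed seed reproduces a
cohort byte for byte.

## Calibration problem sizes

The calibration routines (`meqtl.calibration`) use desk-scale stand-ins
chosen to keep each check in the minutes range on one CPU: null-scan
FDR uses 20 scans of 2,000 probe sets with ~40–50 cis SNPs each at
n = 38 (~10⁵ tests per scan); parameter recovery uses 100 replicates of
30 probe sets with five planted effects of 1.5× the noise sd at
MAF 0.3; the LMM null calibration uses 2,000 likelihood-ratio tests at
n = 181. Under a complete null every discovery is false, so the
empirical FDR over replicates equals the fraction of scans reporting
any hit; with ~10⁵ pooled tests per scan this is a ~5%-probability
event per scan under perfect calibration, so its 20-replicate estimate
is itself noisy — an observed 0/20–2/20 is the expected range.

## Known limitations

- The residual-df convention of the original dosage-regression
  software cannot be verified from published tables; `n − columns`
  is declared and used throughout.
- Storey π₀ via spline extrapolation can dip slightly below 1 on pure
  null data (observed ≈ 0.986–1.0 at m = 10⁴), marginally liberal; the
  small-m fallback π₀ = 1 covers the regimes where this matters most.
- The mixed model supports family sizes ≤ 2 (twin design); larger
  pedigrees would need general block inverses.
- The matched-permutation sampler relaxes tolerances for unmatched
  SNPs rather than failing; heavy relaxation is logged and counted.
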