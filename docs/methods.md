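# Methods

## Scope and data model

The package pools case–control expression evidence for one index gene
across K independent cohorts, assesses its diagnostic accuracy, and screens
all genes for differential expression and co-expression with the index.  A
cohort is a genes × samples matrix of log2 expression with a case/control
label per sample; studies without raw data enter as per-arm (n, mean, SD)
summaries.  Inclusion rules: both groups present, each with n ≥ 3.
Matrices are assumed platform-normalized upstream; the package applies (or
auto-detects the need for) a log2(x + 1) transform only.  The +1 offset
admits zero intensities; auto-detection treats a matrix whose maximum
exceeds 50 as un-logged (overridable).  Probe-level matrices collapse to
gene level by keeping the probe with the largest mean across samples, which
preserves dynamic range better than averaging correlated probes.

## Per-study statistics

**Location test.** A two-sided F-test of the variance ratio at α = 0.05
gates the choice of test: variances compatible → pooled-variance Student's
t; otherwise Mann–Whitney U (exact permutation null for combined n ≤ 12 and
no ties, else the tie-corrected normal approximation with continuity
correction).  Two constant, equal arms return p = 1 by convention.

**Effect size.** Cohen's d with pooled SD; Hedges' g = J·d with
J = 1 − 3/(4N − 9) is the default because cohorts in this design are often
tiny (n as low as 4 per arm) and d overestimates the population effect
there.  The sampling variance v = N/(n₁n₀) + y²/(2N) is evaluated at the
chosen estimator.  Sign convention: case minus control.

## Random-effects pooling

Fixed-effect weights wᵢ = 1/vᵢ give the pooled mean, Cochran's
Q = Σwᵢ(yᵢ − μ̂)², and I² = max(0, (Q − df)/Q)·100.  The between-study
variance uses the DerSimonian–Laird moment estimator
τ̂² = max(0, (Q − df)/C), C = Σwᵢ − Σwᵢ²/Σwᵢ; random-effects weights are
1/(vᵢ + τ̂²).  Confidence intervals are normal-theory (±1.96·se) without
the Knapp–Hartung adjustment, matching the long-standing defaults of the
STATA metan toolchain this workflow descends from.  Known limitation:
normal-theory DL intervals undercover slightly when τ² dominates the
within-study variances at moderate K — measured at ≈ 0.926 for K = 13,
τ = 1, v ∈ [0.1, 0.3] (50,000-replicate check); Knapp–Hartung would fix
this but changes the convention.  Heterogeneity is flagged in reports at
Q-test p < 0.10 (conventional) with p also printed for stricter readings.

The internal pooling core operates on arrays along the last axis with a
validity mask, so the genome-wide screen (thousands of genes × cohorts) and
the Monte-Carlo studies use the same implementation as the public
single-series API.  The DL estimates were cross-checked against R metafor's
`rma(method="DL")` to 1e-9 on a fixed 5-study set.

**Sensitivity and subgroups.** Leave-one-out re-pools each K−1 subset and
reports the omission minimizing residual I², identifying the dominant
heterogeneity source.  Subgroup pooling is random-effects within label; a
singleton subgroup degrades to its own study with a `singleton_subgroup`
flag rather than erroring.

**Publication bias.** Egger's test regresses the standardized effect
yᵢ/√vᵢ on precision 1/√vᵢ; the intercept is tested with k − 2 df.  Begg's
test computes Kendall's S between the variance-standardized deviates
uᵢ = (yᵢ − μ̂_F)/√(vᵢ − se_F²) and vᵢ; for k ≤ 8 the exact permutation
null is enumerated, otherwise S is referred to the no-tie null variance
k(k−1)(2k+5)/18 without continuity correction (exact enumeration of the
k = 10 null shows this holds type-I error at 0.047).

## Diagnostic meta-analysis

Per cohort, continuous expression is dichotomized at the Youden-optimal
threshold (max sensitivity + specificity − 1, orientation "high expression
calls a case", ties to the smallest threshold); the scan is rank-based, so
the resulting 2×2 is invariant to monotone transforms.  The per-study AUC
is the Mann–Whitney statistic computed from midranks.

Tables containing a zero cell get a 0.5 continuity correction on all four
cells.  Pooling operates on (logit sens, logit spec) with within-study
variances 1/tp + 1/fn and 1/fp + 1/tn: each margin is pooled by DL random
effects, and the between-study covariance comes from the method of moments
(the sample covariance of the observed logits; the within-study covariance
is zero for independent binomial margins), with the implied correlation
clipped to |ρ| ≤ 0.999.  The summary curve is the implied between-study
regression of logit sensitivity on logit FPR, slope −cov_b/τ²_spec; when
the studies show no specificity spread the curve degrades to the flat line
through the summary point (flagged `no_threshold_spread`) — in that regime
a full-range sROC is genuinely unidentified, which is why both the full
trapezoidal AUC over (0,1) and the AUC restricted to the observed FPR range
are reported.  Likelihood ratios and the DOR are evaluated at the summary
point with delta-method CIs on the log scale (margins treated as
independent for the CI; the point identities PLR = sens/(1−spec),
NLR = (1−sens)/spec, DOR = PLR/NLR hold exactly).  The Moses–Littenberg
model (OLS of D = logit TPR − logit FPR on S = logit TPR + logit FPR) is
the fallback for k < 3; zero S-spread (identical operating points) falls
back to the symmetric constant-DOR curve rather than erroring, since the
symmetric fit is well-defined there.

## Genome-wide screen

Per-gene pooled SMDs reuse the vectorized DL core; genes contribute per
cohort only where present with positive pooled SD, and need at least
`min_k` = 3 cohorts (τ̂² is meaningless below that).  Correlations with the
index gene are Pearson across all samples of a cohort — cases and controls
mixed, matching how co-expression is computed on raw matrices in this
design; a within-group mode exists for users worried about group-driven
inflation.  r is clamped to |r| ≤ 0.9999 before z = atanh(r)
(variance 1/(n − 3)), pooled by DL across cohorts, back-transformed; p
tests pooled z ≠ 0.  Screening thresholds are strict inequalities —
SMD > 1 (up), SMD < −1 (down), |r| > 0.5 with p < 0.05 (positive/negative
co-expression) — and no multiple-testing correction is applied; both
conventions are recorded in the output metadata.  Intersections (up ∧
positive, down ∧ negative) and the top positively co-expressed partner
(ties lexicographic) complete the screen.

## Synthetic generator

The generator is the package's ground-truth instrument, not a fixture.  Its
defaults define the study conditions: 9 cohorts × (20 case + 20 control),
500 genes, index gene at grand-mean SMD θ = 2.5 with between-cohort SD
τ = 1.0, twenty partner genes at loading λ = 0.8, 10% of background genes
differentially expressed with effects ~ N(0, 1.5²), unit residual SD,
baselines ~ N(7, 1) on the log2 scale — mirroring a typical
nine-microarray meta-analysis of a strongly upregulated gene.

Per cohort k, the index effect δₖ ~ N(θ, τ²) shifts cases by δₖ·σ.  A
partner with loading λ is λ·z + √(1 − λ²)·ε around its baseline, where z is
the cohort-standardized index signal — so the partner's correlation with
the index has expectation λ directly (closed-form truth for recovery
tests), and partners inherit an attenuated group effect through z, as real
co-expressed genes would.  Residuals are Gaussian by default with a
t(3 df) contamination option.  One master seed spawns per-cohort child
streams, so cohort sets are reproducible independent of generation order.
Literature-style studies draw raw arms N(assay_smd, 1) vs N(0, 1) and
summarize them, letting subgroup contrasts (e.g. microarray ≈ 0.9 vs
PCR/ELISA ≈ 7.4) be planted directly.  Diagnostic tables are independent
binomials tp ~ Bin(n, sens), tn ~ Bin(n, spec).

What the generator does *not* emulate: probe-level artifacts, batch and
platform effects, non-Gaussian expression distributions (beyond the t
option), correlated background genes, or missingness patterns.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to everything real microarrays do.

## Validation design and problem sizes

Oracles are closed-form where possible (two-study pooling, Hedges J, the
four-pair AUC), exact enumeration where feasible (Begg permutation null,
Youden threshold scan, Mann–Whitney AUC vs brute force), and independent
fits otherwise (OLS via hand normal equations for Egger and Moses; metafor
reference values for DL).  Monte-Carlo studies run at sizes chosen for
tight error bars at interactive runtimes: DL parameter recovery uses 5,000
summary-level replicates (k = 13, θ = 2.5, τ = 1, v ~ U(0.1, 0.3)), so the
MC standard error on the CI-coverage estimate is ≈ 0.004; the summary-level
design isolates the pooling estimator from the separately-tested SMD
estimation chain (raw-data SMD meta-analysis carries a small negative
correlation bias between the estimate and its variance, which module tests
cover).  Bias-test calibration uses 2,000 nulls at k = 10; sROC recovery
200 replicates at the planted operating point (0.63, 0.79); the screen runs
once at the default study conditions.  The full suite runs in a few
seconds on one CPU.

## Degenerate inputs and numerical conventions

Zero pooled SD → `degenerate_study` error (skipped silently per gene in the
vectorized screen); both arms constant and equal → test p = 1; Begg
variance floor at 1e-12 with a warning when vᵢ ≤ se_F²; Egger refuses
identical variances (`no_precision_spread`); |r| = 1 clamped with a
`degenerate_corr` flag; I² truncated at 0; report JSON rounds floats to 10
significant-decimal places so identical runs are byte-identical across
platforms; timestamps live in a separate `run_info.json` to keep reports
reproducible.
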