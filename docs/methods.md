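# Methods

## The count model

Differential expression is fitted per gene as a negative-binomial GLM with a
log link:

    K_gs ~ NB(mu_gs, alpha_g),        Var(K) = mu + alpha * mu^2
    log mu_gs = x_s' beta_g + log s_s

`x_s` encodes the study design, `s_s` is the sample's size factor (entered
as an offset).  Two design matrices are built in:

- **paired** (single-status series): intercept + dog + biopsy, with biopsy 1
  as reference.  The dog factor absorbs between-animal baselines — the
  pairing — so the `biopsy[b]` coefficient is the within-dog log fold change
  of biopsy *b* over biopsy 1.  Pairwise contrasts `S_vs_P` (biopsy 2 − 1),
  `R_vs_S` (3 − 2) and `R_vs_P` (3 − 1) are linear combinations of those
  coefficients.
- **interaction** (two-arm cohort): intercept + dog + time + status:time.
  Dogs are nested within regression status, so the per-dog intercepts absorb
  the status main effect; `time` is the biopsy-2 indicator and `status:time`
  the extra biopsy-2 effect in regressive dogs.  The regressive-arm B2/B1
  change is `time + status:time`; the interaction test is the Wald test of
  `status:time` alone, thresholded at raw p < 0.05 (an adjusted-p variant is
  available behind a flag).

**Size factors** are median-of-ratios against the per-gene geometric-mean
reference profile, restricted to genes positive in every sample (falling
back, with a warning, to genes positive in at least half the samples), and
rescaled to geometric mean 1.

**Low-expression filter.**  Genes in the lowest 40% of row sums are removed
before dispersion estimation and testing.  The threshold is the upper
empirical quantile boundary (`np.quantile(..., method="higher")`) and genes
tied with it are retained, so a constant row-sum vector keeps every gene.
Removed genes carry an explicit not-tested marker and never enter the BH
denominator.

**Dispersion.**  A Poisson pilot fit supplies fitted means; the per-gene
estimate is the Pearson method of moments,
`alpha_g = sum_s((k - mu)^2 - mu) / mu^2 / (n - p)`.  A trend
`alpha(mean) = a0 + a1/mean` is fitted across genes by least squares with one
outlier-trimming pass, and the default working dispersion is the **trend
value** at the gene's mean, clamped to [1e-8, 10].  Rationale: with 6–12
samples and 4–8 coefficients the per-gene estimate has only a few degrees of
freedom; simulation shows the pooled trend gives a well-calibrated Wald test
(interaction type-I ≈ 0.035–0.04 at the 0.05 cut), whereas the raw gene-wise
estimate is anticonservative (~0.13) and the conservative max(gene, trend)
sharing rule over-shrinks (~0.027).  Both alternatives remain selectable
(`method="gene" | "max"`).

**Fitting** is iteratively reweighted least squares, vectorised across genes
(the design matrix is shared): working weights `w = mu / (1 + alpha*mu)`,
at most 50 iterations, convergence at max |Δcoef| < 1e-8, linear predictor
clipped to ±30, a 1e-10 ridge jitter on the normal equations.  Non-converged
genes are marked not-tested and counted in a warning.  A per-gene
statsmodels GLM (NegativeBinomial family, fixed alpha, offset) serves as the
independent oracle in the test suite; agreement is to ~1e-4 in the
coefficients.

**Testing.**  Wald statistics `c'beta / se(c'beta)` are referred to the
large-sample normal (the convention of count-model DE packages).  A
t-reference with n − p degrees of freedom is available via `df_mode="t"` but
is not the default: at these sample sizes its p-value floor (e.g. ~0.005 at
2 residual df) exceeds what BH at 0.01 can ever reject, i.e. it has no power
by construction.  BH adjustment is the classic step-up (via statsmodels),
applied within each contrast over tested genes only.  Significance calling
is strict on both axes: |FC| > 10 and adjusted p < 0.01.

## Temporal classes and signatures

Directed significant sets ({gene: ±1}) from the three pairwise contrasts are
combined by precedence: **early** = S vs P members; **late** = R vs S
members not in S vs P; **progressive** = R vs P members in neither.  The
classes are disjoint by construction, and a gene's direction suffix comes
from its qualifying contrast (direction conflicts across contrasts are
resolved by that contrast and flagged, not dropped).

The **candidate signature** is the intersection of the regressive-arm B2/B1
significant set with the interaction-significant set; the **core signature**
additionally requires significance in the regressing index case and absence
from the non-regressing one.  Venn percentages are reported as percent of
the first set, truncated (not rounded) to one decimal — the reporting
convention this analysis follows (e.g. 648/1016 = 63.78% appears as 63.7%).

Heatmap matrices are `log2(x + pc) −` mean over baseline samples of
`log2(x_b + pc)` (the mean of the logs, i.e. relative to the baseline
geometric mean), default pseudocount 1 on normalised counts, rows sorted
descending by the mean relative expression of the non-baseline samples.
Fold-change concordance between experiments is the sample Pearson r over
genes tested in both.  Outlier ranking regresses one condition's
`log2(x+1)` mean expression on the other's and ranks by absolute OLS
residual.  The signature-enrichment score (mean within-gene z-score per
sample, groups compared by Wilcoxon rank-sum) is a deliberately generic
stand-in: no specific enrichment method is prescribed for this analysis, so
the score should be read as relative, not canonical.

## Transcript origin and qPCR burden

A somatic biallelic site votes TUMOR if its tumour-allele fraction is ≥ 0.8,
HOST if the host fraction is, and abstains otherwise; only sites with depth
≥ 8 count.  A gene is called when ≥ 2 informative sites exist and all
non-abstaining votes agree — unanimity, not majority, reflecting the
conservative manual review the caller replaces; everything else is
AMBIGUOUS.  The depth and majority defaults are declared free parameters
(no published threshold exists to recover).  Note one deliberate
non-monotonicity: raising `min_depth` can silence a dissenting low-depth
site and thereby convert AMBIGUOUS into a call; raising `min_variants` can
only withdraw calls.  Genes deleted or truncated in the tumour genome are
treated as absolute host markers via a lookup list.

qPCR quantities invert the fitted standard curve
`Ct = slope·log10(q) + intercept` (least squares over ≥ 3 distinct standard
concentrations; efficiency = 10^(−1/slope) − 1), after averaging triplicate
Cts arithmetically.  Target quantities are normalised to the reference gene
(ACTB in the study) and tumour burden change is the ratio of normalised
ratios between biopsies (undefined, not zero, when the baseline ratio is 0).

## Meta-gene methylation profiles

Coordinates are 0-based half-open internally (GTF converted on read;
bedGraph native).  Each gene yields seven strand-aware feature regions:
≤ 2 kb upstream flank, first exon, first intron, internal exons, internal
introns, last exon, ≤ 2 kb downstream flank (first/last by transcription
order; flanks clipped at chromosome bounds).  Single-exon genes define only
the flanks and their one exon; two-exon genes lack internal features; absent
features are excluded from list means, never zero-filled.  The 2 kb upstream
flank doubles as the promoter proxy.

Each feature's concatenated length is split into 20 exactly equal bins
(fractional-base boundaries when the feature is shorter than 20 bp — the
140-bin grid stays rectangular), traversed 5′→3′.  Bin values are
length-weighted means of the piecewise-constant coverage, with uncovered
extent contributing 0; the implementation uses prefix integrals and is
checked against a per-base accumulation oracle to 1e-9.  Tracks are scaled
to global mean signal 1 before profiling to remove between-sample coverage
differences (no between-sample scaling is prescribed; this choice is
recorded in output metadata).

Profiles are normalised by subtracting, per biopsy per bin, the arithmetic
mean over genes not expressed in any biopsy (strict zero-count rule; a
median baseline and a CPM-threshold expression rule sit behind flags).  The
**demethylation score** of a gene for a feature is *minus* the mean of its
20 normalised bin values, so lower methylation than baseline scores higher —
a declared sign convention, since no algebraic definition exists to recover.
Boxplot statistics are median and linear-interpolation quartiles with Tukey
whiskers (most extreme points within 1.5 × IQR); boxes summarise per-gene
feature means (a pooled per-bin variant is available behind a flag).

## The synthetic generator

`SimulationConfig` defaults mirror the study at desk scale: 3 regressive +
3 non-regressive dogs, 3 biopsies, 2,000 genes, NB dispersion 0.05 (typical
bulk RNA-seq), planted log2FC 4 (16-fold, comfortably past the 10-fold
threshold), 5% of genes per temporal class, 5% silent genes (the methylome
baseline), dog effects as additive log-scale offsets (sd 0.2), size factors
uniform in [0.5, 2].  Trajectories: early genes shift at biopsies 2 and 3,
late at biopsy 3 only, progressive by half at biopsy 2 and fully at
biopsy 3 — the progressive ramp is a modelling choice (no quantitative
trajectory is published) chosen so progressive genes cross 10-fold only over
the whole course.  Shifts apply only in regressive dogs unless
`time_effect_both_arms` is set (the interaction-null configuration).

Methylation tracks are a smooth positive step signal (25 bp steps, mean 1,
smoothed noise sd 0.1) shared across biopsies plus small per-biopsy noise
(sd 0.02); planted genes lose 0, e/2, e of signal within the target feature
at biopsies 1, 2, 3, so the planted demethylation trajectory is monotone.
Variant pileups give each gene 2–6 exonic biallelic sites at depth 10–60;
tumour-origin genes emit the tumour allele with probability 1 − error.
qPCR tables are generated from the ideal log-linear curve with slope
−1/log10(2) (100% efficiency) unless told otherwise.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: mapping and duplicate artifacts, GC/length
biases, dispersion–mean relationships beyond the single trend, batch effects
beyond dog offsets, CpG-density structure in methylation, allele-specific
mapping bias, and qPCR plate effects.  The synthetic checks establish that
the *procedures* are correct and calibrated under their stated model, not
that the model captures every property of sequencing data.

## Validation experiments and problem sizes

`ctvtreg.validation` (backing both `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses: 20 replicates × 2,000 genes for null FDR and
interaction type-I; 6 dogs × 2 biopsies with baselines in [100, 1000] for
effect recovery; 3 dogs × 3 biopsies for temporal recovery; a shared-truth
trio (3+3 dogs two-arm, plus two 2-dog index cases) for the core-signature
chain; 200 random tracks for the bin oracle; 20 replicates × 60 genes for
methylome end-to-end; 300 genes for origin accuracy.  These sizes make the
whole battery run in about a minute while keeping Monte-Carlo error well
below the asserted margins.  Recovery experiments disable the 40% row-sum
filter: with every baseline ≥ 100 the filter would discard 40% of
equally-expressed genes by rank alone (including planted down-regulated
genes, whose row sums shrink by construction), which measures the filter,
not the model — the filter has its own contract tests.

## Known limitations

- No shrinkage of log2FC point estimates (deliberately out of scope); very
  low-count genes can show large, noisy fold changes — the FC > 10 with
  adj-p < 0.01 double cut is the guard.
- The normal Wald reference is mildly conservative at 6 samples (observed
  null type-I ~0.03–0.04 at the 0.05 cut); exact small-sample calibration
  would need resampling, which the paired design's size does not support.
- The enrichment score and the demethylation-score sign are declared
  conventions, not reconstructions.
- Origin calls assume sites are independent and error symmetric; linked
  errors (e.g. mapping bias at a locus) can defeat the unanimity rule.
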