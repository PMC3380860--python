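# Methods

## The problem

Mutations in eIF2B, the guanine-nucleotide exchange factor for the
translation initiation factor eIF2, cause a severe leukodystrophy
(CACH/VWM).  The analysis implemented here asks which transcriptomic changes
in patient fibroblasts are *specific* to the eIF2B-related disorder rather
than shared with other leukodystrophies (OL) or induced by ER stress, and
whether those changes — dominated by mRNA-processing regulators such as the
HNRNP family — have functional consequences on the splicing of glial
maturation genes (PLP1's PLP/DM20 isoforms, GFAP's alpha/delta isoforms) in
the developing brain.

The real study's raw data are private (no public accession), so the package
ships a synthetic-data generator that reproduces the *design* of the study —
two cohorts of 10 matched patient/control fibroblast couples, two treatments
(1 µM thapsigargin ER stress vs ethanol vehicle), a two-channel microarray
with a pooled-control reference, a fibroblast qPCR validation panel, and a
developmental brain autopsy panel — with implanted, known effects.  Every
analysis stage is then validated by recovery of the implanted truth.

## Two-channel normalization

Raw intensities are log-transformed (natural log by default; base is a
recorded provenance option).  The reference correction

    corrected_gi = G_log_gi − R_log_gi + mean_a(R_log_ga)

subtracts the pooled-reference channel array-by-array — removing slide and
labelling effects shared by the co-hybridized channels — and restores the
gene's mean reference level over **all** arrays of the experiment, keeping
values on the absolute log-intensity scale.  "Standardisation" beyond the
log is off by default: the correction already removes array-level effects,
and double-normalizing (per-array z-scaling plus reference correction) would
distort the rate statistic below.  A per-array z-scaling mode exists for
users whose data need it; the choice is recorded in the output provenance.
Whether scaling is applied before or after the correction is the caller's
composition choice; the default pipeline applies none.

Only *characterized* genes enter the statistics; EST and LOC entries are
removed by an explicit annotation filter.

## Gene-wise ANOVA and the specificity selection

Per gene, an additive fixed-effects ANOVA is fitted on corrected values:

* per cohort: status (patient/control) + couple (1..10) + treatment — 40
  arrays, residual df 27;
* cross-cohort: cohort (eIF2B patients vs OL patients) + treatment over the
  40 patient arrays, with couple variance left in the residual.

Designs are balanced and orthogonal, so factor sums of squares are level-mean
contrasts and SS_factors + SS_residual = SS_total; F = MS_factor/MS_residual
with p from the F distribution.  Genes with zero total variance are reported
F = 0, p = 1 (conservative).  The per-factor p-values are converted to
Benjamini–Hochberg q-values (the historical analysis reports an FDR without
naming a procedure; BH is the standard choice and is recorded in the report),
thresholded at q ≤ 0.0012 (0.12%).

The expression rate of a gene is the mean over couples of the
patient/control ratio of corrected log values, treatments averaged within
couples first.  This ratio-of-logs statistic is scale dependent — its
thresholds (under-expressed ≤ 0.9, over-expressed ≥ 1.05) presuppose
baselines near log-intensity 8 — and is applied exactly as defined because
those printed thresholds are part of the method.  The disease-specific set is
the intersection: case-vs-control q ≤ 0.12%, cross-cohort q ≤ 0.12% (the
cross threshold is not separately documented in the source analysis; the
same value is the default and is configurable), and rate outside (0.9, 1.05).

## Enrichment z-score

Category over-representation uses the hypergeometric standard score: with
universe N, category size K, hit list n and overlap k,
μ = nK/N, σ² = n(K/N)(1−K/N)(N−n)/(N−1), z = (k−μ)/σ, significant when
z > 3.  No multiple-testing adjustment is applied to z by default (the z>3
rule is the method); BH q-values over the normal tail are available behind a
flag, as is a binomial-variance approximation.  The universe is an explicit
required input — enrichment depends on it strongly and no canonical universe
ships with the package.

## qPCR quantification

Replicate Cts (2 independent RTs × 2 PCR duplicates) are averaged after
excluding censored reactions (no amplification by cycle 40); replicate
spread > 0.5 cycles raises a QC flag without dropping data.  ΔCt is taken
against B2M (fibroblasts/brain default) or against the arithmetic mean of
several reference Cts (GAPDH+HPRT for SYBR isoform assays) — equivalent to
normalizing expression by the geometric mean of the references; the
combination rule is the package's choice since the source does not state
one.  The couple rate is mean over couples of 2^−(ΔCt_patient −
ΔCt_control); the Methods-section sign (with the leading minus) is used
throughout, since under-expressed genes must give rates < 1.  Per-sample
relative expression is 2^−ΔCt, with censored targets reported as expression
0 (undetectable), never extrapolated.

Group comparisons use the two-sided Mann-Whitney U: the exact null
distribution when the smaller group has ≤ 8 observations without ties, the
tie-corrected normal approximation otherwise.

## Cross-platform concordance

Per gene and cohort, the per-couple microarray log ratio is Pearson-
correlated with the per-couple qPCR log2 fold (−ΔΔCt; this orientation makes
concordant couples correlate positively).  N is the number of retained
couples by default (counting treatment conditions as separate points is a
config option; the convention is recorded).  Couples whose direction of
change disagrees between platforms for ≥ 8 of the 10 panel genes are
excluded first — an operationalization of the narrative exclusion rule in
the source analysis, which names no numeric criterion.  Cohort correlations
are compared by Fisher's Z: Zf = ½ln((1+R)/(1−R)),
z = (Zf1−Zf2)/√(1/(N1−3)+1/(N2−3)), two-sided normal p.

## Isoform ratios

The PLP assays measure PLP alone and PLP+DM20 together, so DM20 is
extrapolated as (PLP+DM20) − PLP on the 2^−ΔCt scale; a negative
extrapolation (possible under noise) is flagged and its ratios excluded,
never clipped.  GFAP is measured as pan-GFAP plus the alpha and delta splice
isoforms, with ratios pan/alpha, pan/delta and alpha/delta.  Ratios are
computed per sample and then summarized (not as ratios of group means; the
alternative order was genuinely open and per-sample ratios were chosen
because they feed the Mann-Whitney test directly).  Stage-wise group effects
are folds of group means with a Mann-Whitney p, reported as not computable
when a group has a single sample.  Censored samples are excluded from
ratios.

## The generator

Log intensities follow
`baseline_g + array_a + shift·1[affected] + stress_g·1[thapsigargin] + ε`,
with the reference channel sharing `baseline_g + array_a` (same slide) plus
independent noise.  Defaults encode the study scale and printed counts: 2000
genes (a 44K-style array down-sampled for desk-scale runs; a full-scale
option exists), 253 differentially expressed genes of which 183 are shared
between cohorts (shift −0.6) and 70 eIF2B-specific, 3 of those over-expressed
with rates drawn in [1.06, 1.07] and 67 under-expressed with rates in
[0.66, 0.88]; a 150-gene ER-stress signature identical across groups
(shift ~ N(0, 0.5) under thapsigargin); baselines N(8, 1.5) clipped below at
3 (the rate scale on corrected log values requires comfortably positive
baselines); measurement noise sd 0.05 and array effects sd 0.1 — asserted as
defaults, not as estimates of the original arrays, whose noise magnitudes
were never published.  Specific-gene shifts are `baseline·(rate−1)`, so the
expected corrected-log-value ratio equals the drawn rate exactly and the
printed thresholds 0.9/1.05 are meaningful.

Per-couple biological variability (`couple_effect_sd`, default 0) adds a
shared lognormal jitter to each implanted fold, propagated to the qPCR
generator through the bundle's `couple_folds`, which is what makes
cross-platform correlations non-degenerate; it defaults to 0 so that
noise-free runs satisfy exact closed-form identities.

qPCR Cts follow `ct0_g − log2(relative expression) + ε` with censoring at 40
cycles recorded by an explicit flag.  The brain panel implants: GFAPdelta
folds 2/4.5/7 (foetus/child/adult) with flat pan-GFAP and GFAPalpha;
PLP-family transcripts censored in control foetal brains, detectable at low
level in mutated foetuses with the PLP+DM20/PLP ratio elevated 2-fold, and
reduced 0.3-fold in mutated postnatal brains; the 13 validation genes 1.5×
up in mutated foetuses and 0.6× down postnatally.  The child control group
defaults to 5 (the autopsy roster lists 3 child controls; 5 gives the
Mann-Whitney test usable power at this scale and is configurable to 3).
All streams derive from one master seed (one stream per output table), so
identical configs reproduce outputs byte-identically.

### What the generator does not emulate

Probe-level structure (one intensity per gene per channel, no multi-probe
summarization), scanner/image artefacts, dye-swap designs, spatial effects,
amplification-efficiency differences between qPCR assays, and real
between-gene correlation structure.  Passing recovery tests therefore shows
the *pipeline arithmetic* is correct under the declared statistical model,
not that the model captures every failure mode of real arrays.

## Problem sizes and numerical choices

Default runs use 2000 genes × 80 arrays; a full pipeline run takes a few
seconds, and the test suite's Monte-Carlo oracles use 10^6 hypergeometric
draws, 200 null FDR simulations and 2000 Fisher-Z calibration replicates.
Tolerances: ANOVA vs least-squares oracle 1e-8 relative; noise-free
closed-form identities 1e-12; Monte-Carlo comparisons at ~3 binomial/normal
standard errors.  Ties in zero-variance detection use a relative threshold
of 1e-12 against the row's sum of squares.

## Known limitations

* The rate statistic inherits the scale dependence of the published formula;
  an intensity-ratio alternative is a deliberate non-goal here because the
  printed thresholds are defined on the published scale.
* The Fisher-Z comparison uses R = +√R² semantics when only R² is known;
  signed correlations should be supplied when available.
* The discordant-couple rule (≥ 8/10 sign disagreements) is a declared
  operationalization of a narrative criterion.
* Published per-gene results that depend on the private raw data or on a
  proprietary annotation database (per-gene FDRs and rates, enrichment z
  magnitudes, published concordance p-values) cannot be reproduced and are
  not asserted anywhere in the package.
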