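# Methods

This note documents the statistical models behind `methclass`, the defaults
and why they were chosen, the synthetic-data generator's assumptions, and
the package's numerical conventions and known limitations.

## Measurement model

A 27K-style array reports, per CpG and sample, a methylated (Me) and an
unmethylated (Um) fluorescence intensity. The β value is
β = Me/(Me + Um + offset) with the platform's standard offset of 100
intensity units, so β ∈ [0, 1) and reads as the methylated fraction. The M
value is log2((Me + α)/(Um + α)) with a pseudo-count α = 1 by default
(configurable); β can also be converted directly via logit2, with values
clamped to [10⁻⁶, 1 − 10⁻⁶]. β is retained as the working scale throughout
because every downstream method here is rank- or beta-distribution-based.

Two categorisations are supported. The reference scheme assigns
unmethylated (UM) for β < 0.2, hemi-methylated (HM) for 0.2 ≤ β ≤ 0.8 and
methylated (M) for β > 0.8. The {0, ½, 1} discretisation uses thresholds
0.3 and 0.7; its source definition leaves β = 0.7 itself unassigned
("> 0.3 and < 0.7" versus "> 0.7"), and we close that gap upward so 0.7 maps
to 1. Discretisation loses power and is provided for comparability, not
recommended.

**No normalisation.** Global methylation genuinely differs between samples,
so quantile/LOWESS normalisation in the expression-array style can remove
true biology. The MA transform (`m = βs − βr`, `a = (βs + βr)/2` on the β
scale; plain log-ratios for log2 expression) is exposed as a diagnostic
only, with the conventional display bands (±0.2/±0.5 for β, ±1/±2 for
expression). Plain β differences, not log-ratios, are used in β mode
because the band thresholds only make sense on that scale. A
variance-stabilising transform would be a natural extension; it is
deliberately out of scope.

## Filtering

* `top_variance_filter(k)` — the k CpGs with largest across-sample variance
  (n − 1 denominator; ties broken by CpG id). β variance peaks for
  hemi-methylated CpGs, so this filter is biased toward HM sites; a test
  documents that bias rather than hiding it.
* `differential_filter(delta=0.2, min_frac=0.3)` — a CpG passes when the
  fraction of tumor samples with |β − mean(normal β)| > delta is at least
  min_frac. "More than 20% methylation" is read as an absolute β difference
  of 0.2 — the natural unit of the β scale — with a strict inequality at
  delta; the rule is unsigned by default, with `hyper`/`hypo` one-sided
  options recorded in the result's criterion (the original rule's
  directionality is ambiguous, so the choice travels with the output).
* `rank_by_test(fwer)` — delegates to the class-comparison scan below.

All three exist both as scikit-learn selectors (`fit`/`transform` on
samples × CpGs) and as functions on the file-layout matrix.

## Class comparison

Per CpG, group differences are tested with the Kruskal–Wallis statistic on
average ranks with the standard tie-correction divisor
1 − Σ(t³ − t)/(N³ − N), referred to χ² with (groups − 1) degrees of freedom.
The scan is vectorised across CpGs (row-wise ranking), which makes
200-replicate null calibrations cheap. Missing values are dropped per CpG;
a group left empty at some CpG is an error, not a silent skip. For very
small groups a seeded Monte-Carlo permutation p-value
(p = (1 + #{H* ≥ H})/(1 + B)) is available behind a flag; exact enumeration
is not attempted.

Family-wise error control defaults to Holm's step-down, which dominates
Bonferroni at the same FWER; Bonferroni is available for strict
comparability with older analyses. By default `differential_cpgs` compares
only the four tumor subtypes (normals excluded); pass `groups` to change
that. In the suite's 200-replicate null calibration (5000 CpGs, 4 × 15
samples) the realised family-wise error is far below the nominal 0.05: with
5000 tests the Holm threshold sits at p ≈ 10⁻⁵, where the χ² approximation
of the rank statistic is conservative for groups of 15.

## Class prediction

`MedianCentroidClassifier` summarises each class by the per-CpG median β of
its training samples (midpoint convention for even counts; NaN-aware) and
assigns a sample to the class whose centroid maximises the Spearman
correlation with the sample profile over its non-missing CpGs (≥ 3
required; a zero-variance profile is an error naming the sample). Exact
correlation ties go to the lexicographically first class and are flagged;
the reported margin (best minus second-best correlation) exposes
low-confidence calls — on real breast-cancer data the Luminal A/B boundary
is the typical weak spot. Because Spearman uses only ranks, predictions are
invariant under strictly monotone transforms of either profile.

The random forest is used strictly off-the-shelf
(`sklearn.ensemble.RandomForestClassifier`, 500 trees, fixed seed) as a
baseline with contract-level guarantees only (determinism under seed,
lexicographic vote tie-break); no bespoke tree code.

Confusion matrices report per-class error = misclassified / class size,
rounded to 2 decimals for display with full precision retained.

## Class discovery

**Hierarchical.** Samples are clustered with complete linkage on
d = 1 − Pearson r; columns are processed in sorted sample-id order so
equal-distance merges break deterministically. Cluster stability resamples
CpGs (features, not samples) with replacement: BP(node) = fraction of B
replicate trees containing the identical sample set. AU p-values use the
two-term multiscale regression — z_r = Φ⁻¹(1 − BP_r) fitted on (√r, 1/√r)
over r ∈ {0.5, …, 1.4}, AU = 1 − Φ(v − c) — fitted only on scales with
0 < BP_r < 1; when BP sits at 0 or 1 on essentially every scale the signed
distance is unidentifiable and the plain BP is reported as the AU value. BP
with B = 1000 is the supported default; the AU machinery is a deliberate
approximation, not a reimplementation of any particular package's
internals, and no rejection rule is imposed on it.

**Recursively partitioned beta mixtures.** Within a component, each CpG j
is an independent Beta(a_j, b_j) variable. EM alternates responsibilities
(computed in the log domain) with per-CpG weighted moment matching:
m, v → a = m(m(1 − m)/v − 1), b = (1 − m)(m(1 − m)/v − 1), with the
variance floored at 10⁻⁶ and shapes at 0.01 so degenerate (constant) data
stays finite. Moment matching is not an exact M-step, so each iteration is
accepted only if the observed-data log-likelihood does not decrease; the
recorded history is therefore monotone up to `tol` (10⁻⁶ default, 500
iteration cap). Two-component fits are initialised from the sign of the
leading principal direction of the centred data (sign fixed by the largest
loading), which is deterministic and invariant to CpG order — no random
restarts by default.

A node splits when BIC(k=2) + `bic_margin` < BIC(k=1), with
BIC = −2·loglik + p·ln(n) and p = 2kJ + (k − 1) for J CpGs; children are
hard-assigned by maximum responsibility and must keep ≥ `min_node` (5)
samples. This is a deliberately simplified re-derivation of recursively
partitioned mixture modelling: binary splits, BIC gating and hard
assignment instead of the original's weighted fuzzy recursion. The leaves
are the methylation classes, so the number of clusters is chosen by the
model. On the generator's defaults the recursion recovers the four planted
subtypes exactly; on null data it returns one leaf.

## Integration

CpGs join expression probes by gene id, either keeping all probes per gene
("maximum") or the probe with the largest expression variance
("most_variant", ties by probe id). Correlation is Spearman with average
ranks, pairwise-complete, ≥ 3 shared samples per pair, reported per pair
with a summary (min/max/mean/median and fraction negative) and optionally
per subtype. TSS windows are closed intervals on the signed distance
(negative = upstream); no strand logic beyond the sign already encoded.
The TSS methylation profile bins per-CpG mean β by signed distance
(100 bp default), reports empty bins as empty, and offers a tricube
running-mean smoother for plotting. Expression "tiers" are bounded by the
1st and 3rd quartile of per-gene mean expression (< Q1 low, Q1–Q3 inclusive
medium, > Q3 high; linear-interpolation quartiles recorded in the output
metadata, since tier boundaries depend on the convention); the common
"tertile" label for this construction is avoided because the classes are
quartile-bounded and unequal.

## Synthetic data generator

The generator defines the package's study conditions. Defaults: 5000 CpGs
(one per gene; the real platform has 27,578 — scaled down so full pipelines
run in seconds), 4 subtypes × 30 tumors (matching the published confusion
matrix's class sizes of 35/25/27/30) plus 8 normals, and 99 planted
subtype-differential CpGs (the size of the published key-CpG list). Each
CpG gets a baseline state drawn with proportions UM 0.55 / HM 0.25 / M 0.20
— a dominant hypo-methylation peak and a minor hyper-methylation peak — and
β is drawn per state from Beta(2,18), Beta(2,2) and Beta(18,2) (means 0.10,
0.50, 0.90). These shapes reproduce the qualitative variance ordering of
real data (HM variance 0.05 ≫ UM/M variance ≈ 0.004; the real-data
counterparts are ≈ 0.03 vs 0.002). Differential CpGs carry a
subtype → state map drawn uniformly over non-constant maps, so all pairwise
contrasts are exercised; normals always keep the baseline state. The
`effect_size` parameter shrinks differential-state means toward 0.5 at
constant concentration, giving a clean difficulty dial for recovery tests;
1.0 (full separation) is the default condition.

Annotation places 78% of CpGs within ±500 bp of the TSS (the platform's
promoter-centric design), the rest uniformly out to ±5 kb, and gives each
gene 1–3 expression probes so both mapping modes are exercised. Expression
is baseline_g − slope·β + noise on a log2-like scale (baseline ~ N(8, 1.5),
slope 4 within the promoter window, attenuated ×0.25 outside, noise sd
0.5), chosen to give strong but not deterministic promoter anti-correlation
at realistic dynamic range.

The generator shares the beta family with the discovery module by design —
that is what makes exact parameter-recovery tests possible — and this must
be kept in mind when reading the results: passing tests show the methods
are implemented correctly and calibrated under a well-specified beta-state
world. Real arrays add probe-chemistry differences, batch and
bisulfite-conversion effects, correlated CpGs within islands, mislabelled
or admixed samples and heavier-tailed noise, none of which are modelled, so
the perfect recovery seen at default effect sizes is an upper bound, not a
forecast. The effect-size distribution of real subtype differences is
unknown; the planted defaults were chosen for testability.

Fixing `SimConfig.seed` makes every output byte-identical. The pipeline
runner records a config hash, seeds, version and per-stage row counts in a
manifest without timestamps, so a rerun with the same config reproduces the
run directory exactly.

## Numerical conventions and edge cases

* Variances use the n − 1 denominator everywhere they are reported.
* Matrices round-trip through TSV at 6 significant digits; "NA" marks
  missing; rows with > 20% missing are dropped at load (configurable) and
  pairwise-complete observations are used downstream.
* Reference categorisation at the boundaries: [0, 0.2) / [0.2, 0.8] /
  (0.8, 1].
* β-mixture inputs are clamped to [10⁻⁶, 1 − 10⁻⁶]; EM tolerance 10⁻⁶.
* Ties: average ranks (tests and Spearman); lexicographic tie-breaks for
  class assignment and feature selection are deterministic and documented
  on each function.

## Problem sizes used by the test suite

Unit tests run on a 600-CpG, 53-sample down-scaled configuration; the
acceptance checks use the full default conditions (5000 CpGs, 128 samples)
and a 200-replicate null calibration. These sizes were chosen so the whole
suite completes in about a minute while keeping every statistical check at
a sample size where its tolerance is meaningful.

## Known limitations

* The recursive partition is "RPMM-style", not a clone; level-weighted
  fuzzy recursion is not implemented.
* AU p-values are a two-term approximation and should be treated as
  indicative; BP is the supported stability measure.
* No batch-effect, probe-type (Infinium I/II) or bisulfite-conversion
  modelling, matching the scope of the analysis the package implements.
* Headline counts from the original cohorts (numbers of differential CpGs,
  genome-wide correlation ranges) depend on those specific datasets and are
  not reproduced here; the package reproduces the methods and their
  in-table arithmetic, and validates the statistics on synthetic data with
  known truth.
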