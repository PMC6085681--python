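# Methods

This note documents the statistical model behind `methpair`, what the
synthetic-data generator does and does not emulate, the numerical choices
baked into the code, and the package's known limitations.

## Paired differential model

The unit of inference is the within-patient contrast. For probe *j* and
patient *i* the paired difference d<sub>ij</sub> = x<sub>ij</sub><sup>D</sup> −
x<sub>ij</sub><sup>N</sup> is formed either on the β scale or (default) on the
M scale, M = log₂ β/(1−β), and tested with a one-sample t-test against zero
(df = n<sub>pairs</sub> − 1, two-sided). The M scale is used for testing
because array β values are heteroscedastic — their variance shrinks toward
the 0/1 boundaries — while the effect threshold is always evaluated on the
β scale, where a fixed |Δβ| has a direct biological reading as a shift in
methylated-cell fraction.

A probe is called a DMP when |Δβ| > Δ (strict) **and** BH-adjusted p ≤ q,
with defaults Δ = 0.15, q = 0.05. The strictness convention follows the
symbols of the rule (">" for the effect, "≤" for the FDR). Direction is the
sign of Δβ. Design choices worth flagging:

- **No variance moderation.** The test is a plain paired t, not a moderated
  (empirical-Bayes-shrunken) linear model. With ~24 pairs and an effect
  floor of 0.15 the joint rule is dominated by the Δβ filter, so moderation
  buys little here; exposing a single, fully specified test keeps every
  p-value reproducible by hand. This is a deliberate simplification.
- **Degenerate probes** (zero variance of differences) get no p-value and
  can never be DMPs; assigning them p = 1 would manufacture confidence in a
  quantity the data cannot estimate.
- **Missing values** drop that patient for that probe only; probes with
  fewer than 3 complete pairs are excluded from testing.
- The scale of the test (`m` vs `beta`) is an exposed parameter because
  either convention is defensible; the Δβ threshold is unaffected.

BH adjustment is delegated to `statsmodels.stats.multitest` (the test suite
verifies it against a brute-force p·m/rank + cumulative-minimum
implementation); NaN entries pass through without affecting the adjustment
of tested probes.

## Probe filter cascade

Rules run in a fixed order — control probes, detection failure, low bead
count, non-CpG probes, sex chromosomes, polymorphic sites — and each probe
is charged to the *first* rule that removes it, so the per-rule tolls sum
exactly to the number removed. The detection/bead quota is "fails in more
than 5% of samples"; strict ">" was chosen because the alternative "≥" is
equally defensible and the quota is therefore an exposed parameter
(`sample_quota`), not a constant.

## Normalisation surrogates

Two standard array-preprocessing steps are implemented as deliberately
simple, fully specified surrogates, and are labelled as such in logs and
run summaries:

- **Design-bias correction** (in place of a beta-mixture quantile method):
  per sample, type-II probe β values are quantile-mapped onto the empirical
  distribution of that sample's type-I probes via mid-ranks ((r − ½)/n) and
  linear interpolation. The map is monotone, so within-sample type-II
  rankings are preserved; type-I values are untouched. A sample with fewer
  than 50 type-I probes is refused, since its empirical quantile function
  would be too coarse to map onto.
- **Batch adjustment** (in place of empirical-Bayes batch correction): on
  the M scale, each probe's per-batch values are z-scored against the batch
  mean/SD and rescaled to the probe's pooled mean/SD. This provably removes
  additive per-batch offsets and multiplicative per-batch scale differences
  — exactly the structure the generator injects — and preserves each
  probe's pooled mean to float precision. A batch with one sample is
  refused (its SD is undefined); a probe with zero pooled spread is left
  unchanged.

These surrogates are not drop-in replacements for the published methods on
real array data; they are the simplest transforms whose correctness can be
verified analytically, which is what a ground-truth-driven pipeline needs.

One property of the quantile-mapping surrogate deserves emphasis: like any
rank-based normaliser it assumes type-I and type-II probes share a
distribution *within each sample*. Strong differential signal concentrated
in type-II probes violates that assumption sample by sample, and mid-range
values — where the bimodal β distribution is sparse — are mapped through
coarse empirical quantiles, which attenuates part of the spiked effect
(in the default synthetic study, full-pipeline recovery drops from 100% to
roughly 78% of spikes relative to calling DMPs on filtered-but-unnormalised
data). The generator injects no design-type bias, so the recovery and
calibration benchmarks are measured at the caller on the filtered matrix,
where the quantity being tested — the joint |Δβ|/FDR rule — is isolated
from normaliser distortion. On real arrays, where type-II bias is real and
differential probes are a small minority, the trade-off runs the other way.

## Interval engine

All coordinates are 0-based half-open (BED native); 1-based inclusive input
must be converted at the boundary, and probes are length-1 intervals.
Promoters are 1500 bp windows: [t−1000, t+500) on the + strand and the
strand mirror [t−499, t+1001) on the − strand, so 1000 bases always lie
transcription-upstream. Windows are truncated at position 0 with a warning.
CpG-island tiers use the platform convention — shore = (0, 2000] bases from
the nearest island edge, shelf = (2000, 4000], open sea beyond — with the
nearest island governing; a probe one base past an island edge has distance
1. Region classes resolve multi-gene conflicts with promoter > exon >
intron > intergenic precedence, promoters first because the promoter is the
regulatory unit the downstream aggregation is built on; the precedence is a
documented convention, not a claim about biology.

Promoter-level aggregation reports, per gene, its DMP count and mean Δβ; a
gene whose DMPs disagree in sign is labelled *mixed* and excluded from
direction counts rather than averaged into a false direction. Both the
≥1-DMP and a configurable ≥`min_dmps` selection are reported, since either
can reasonably define a "differentially methylated promoter".

## Enrichment statistics

All over-representation tests are hypergeometric upper tails
P(X ≥ k | N, K, n) with BH across categories, where the background N is
always the post-filter analyzable probe (or gene) universe — not the full
array — because enrichment claims are relative to what could have been
called. Loci with zero background probes are emitted with K = 0, p = 1 and
an `untestable` flag rather than dropped, so the output always has one row
per input locus. The locus test conditions on the whole analyzable
background (not on pooled locus membership); the pooled all-loci record is
reported alongside. The gene-set test is a plain hypergeometric over
user-supplied sets; no composite "enrichment score" of any web service is
computed. Fisher's exact test (two-sided, by enumeration of margin-fixed
tables at most as probable) handles small contingency tables; a zero margin
returns p = 1 by convention with a warning.

## Histopathology stratification

For a binary feature, patients with a missing value are dropped *for that
feature only*, the remaining pairs are split into present/absent strata
(each must keep ≥ 3 pairs), and the full DMP analysis is rerun per stratum.
A probe is **unique** to a stratum when it passes the joint |Δβ|/FDR rule
there and fails it in the counterpart. "Fails the joint rule" was chosen
over "counterpart adjusted p > 0.05 alone" because it is symmetric with the
DMP definition itself; the stricter variant is available via
`counterpart_rule='padj'`. Note the uniqueness sets are threshold
exceedances, not interaction tests: a probe just above threshold in one
stratum and just below in the other is "unique" without the strata being
significantly different from each other. This mirrors how such sets are
defined in practice and is why downstream interpretation leans on the
cross-feature intersections and ground-truth benchmarks rather than on any
single membership.

The rete-peg screen correlates lesional β (disease samples only — the
morphology being correlated is lesional; `include_normal=True` switches to
the paired β difference) with the per-patient maximum rete-peg length:
Pearson r, two-sided p from t = r√((n−2)/(1−r²)), tiers at |r| ≥ 0.4
(`correlated`) and |r| ≥ 0.6 (`high`), both gated on p ≤ 0.05. The absolute
value is intentional: inverse correlations (methylation silencing a gene
needed for the phenotype) are as informative as direct ones. Constant
vectors are excluded with a flag. Top-k selection for PCA ranks by
ascending adjusted p, ties by descending |Δβ|, then probe ID — a total
order, so the selection is deterministic.

## Synthetic-data generator

The generator emulates the *structure* of a paired skin-methylation study,
with every draw derived from one seed:

- **Baseline.** Per-probe baseline β from a bimodal mixture (Beta(5, 45)
  and Beta(42.5, 7.5), equal weights; modes ≈ 0.1 and ≈ 0.85), mimicking
  the unmethylated/methylated bimodality of array data.
- **Noise.** Gaussian on the M scale (default SD 0.5), mapped back through
  the inverse logit, so β stays strictly inside (0, 1) with no clipping.
  The default SD is a free parameter of the generator, not an estimate from
  any dataset. A per-patient random effect (default SD = noise SD / 2) is
  shared between a patient's two tissues — it is what makes the paired
  design pay off. Batches contribute additive M-scale offsets (default two
  batches at 0 and +0.3), assigned per patient so pairs are never split
  across batches.
- **Spikes.** Hyper/hypo DMPs shift the lesional mean by exactly ±Δβ on the
  β scale *before* noise; spiked baselines are drawn from a band chosen so
  both tissue means stay inside (0.02, 0.98), and a configuration that
  cannot satisfy this is refused rather than clipped. The default spike set
  is 500 hyper + 300 hypo (a 62.5% hyper skew) at Δβ = 0.25 across 20,000
  probes and 24 pairs — the conditions all recovery benchmarks run under.
- **Feature-linked probes** receive their shift only in the lesional tissue
  of feature-positive patients. The default histopathology preset encodes a
  24-patient cohort with Munro's microabscess 11 present / 10 absent / 3
  not assessable, focal hypergranulosis 7/17 and Kogoj's microabscess 9/15,
  plus a continuous rete-peg length, uniform on 150–600 µm.
- **Length-tracking probes** have lesional target β = c + s·slope·(L − L̄)
  with sign s = ±1, c ≈ 0.5, and the normal tissue held at c. The default
  slope of 0.001 β/µm comes from a variance budget: the per-sample β-scale
  noise near β = 0.5 is ln2 · β(1−β) · σ<sub>M,total</sub> ≈ 0.097 with
  σ<sub>M,total</sub> = √(0.5² + 0.25²), and a population correlation of
  r ≈ 0.8 needs a signal SD of 0.097 · 0.8/√(1−0.8²) ≈ 0.13, which a
  uniform 150–600 µm length (SD ≈ 130 µm) delivers at slope ≈ 0.001.
- **Geometry.** Probes are laid along six synthetic autosomes plus chrX/Y;
  promoter-class probes come in 1–4-probe clusters, each backed by a
  synthetic transcript whose promoter window provably contains the cluster;
  CpG islands are interspersed so all four island-relation tiers occur;
  susceptibility-like loci are contiguous probe runs covering exactly
  `round(psors_fraction · n_probes)` probes (default 25% across 10 loci).
  The default region mix is intron-heavy (40% intron, 25% promoter, 25%
  intergenic, 10% exon). Small fractions of probes are flagged as controls,
  non-CpG, polymorphic, sex-chromosomal, detection-failing or bead-poor to
  exercise the filter cascade; ground-truth probes are always drawn from
  the clean autosomal pool, and all ground-truth categories are disjoint by
  construction.

What the generator does **not** emulate: realistic probe-level variance
heterogeneity, spatial correlation along the genome, LD/SNP structure,
cell-type composition differences between tissues, dye/intensity-level
artefacts, or genuinely nonlinear β–phenotype relations. Passing benchmarks
therefore demonstrate that the pipeline's logic is correct under its stated
noise model — not that its operating characteristics (sensitivity, FDR)
transfer to real tissue data, where between-patient heterogeneity is
heavier-tailed and effects are correlated.

## Numerical choices

- Logit clamp ε = 10⁻⁶ keeps M finite at β ∈ {0, 1} with negligible
  interior distortion; the β↔M round trip is exact to < 10⁻¹² over
  [10⁻⁵, 1−10⁻⁵].
- Hypergeometric tails come from `scipy.stats.hypergeom.sf` (log-space
  internally); the suite pins them to exact rational enumeration at
  N ≤ 50 within 10⁻¹⁰.
- Clustering is Euclidean/complete-linkage (`scipy.cluster.hierarchy`),
  cut at two clusters; purity is the best-matching agreement with tissue
  labels, and an all-zero distance matrix is reported as degenerate rather
  than clustered. PCA is a centered SVD with variance fractions normalised
  over the non-trivial spectrum (they sum to 1 by construction).
- Benchmarks in the test suite run at reduced problem sizes (1,500–20,000
  probes) chosen so each property is measured with comfortable margin;
  the acceptance script uses the full default conditions.

## Limitations

- The normalisation steps are surrogates (see above); results on real
  array data should use the field's standard preprocessing and enter this
  pipeline at the β-matrix stage.
- No region-level (DMR) smoothing: aggregation stops at promoter windows.
- No cell-composition adjustment; whole-tissue contrasts confound
  methylation change with composition change, which a paired design
  mitigates but does not remove.
- The plain paired t-test is anti-conservative for very small strata
  compared to moderated alternatives; strata are therefore floored at
  3 pairs and the joint rule's Δβ filter provides the main false-positive
  control.
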