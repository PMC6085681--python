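# methpair

Paired differential DNA-methylation analysis for lesional vs adjacent-normal
tissue studies, built around the design used in epigenome-wide association
studies of psoriasis: each patient contributes a diseased and an adjacent
histologically normal skin biopsy profiled on a bead array, and every
question is asked within-patient.

The package is aimed at analysts who have (or want to emulate) a probe-level
β-value matrix with paired sample metadata and who need, on top of the DMP
calls themselves, the study-level readouts that make such a dataset
interpretable: susceptibility-locus enrichment, promoter-level aggregation,
histopathology-stratified "unique DMP" calling, and a methylation–morphology
correlation screen.

## The model

For probe *j* and patient *i*, let β<sub>ij</sub><sup>D</sup> and
β<sub>ij</sub><sup>N</sup> be the methylation fractions in disease and
adjacent-normal tissue. The effect size is the mean paired difference on
the β scale,

&nbsp;&nbsp;&nbsp;&nbsp;Δβ<sub>j</sub> = mean<sub>i</sub>(β<sub>ij</sub><sup>D</sup> − β<sub>ij</sub><sup>N</sup>),

while the test statistic is a paired one-sample t on the variance-stabilised
M scale (M = log₂ β/(1−β)). Raw p-values are Benjamini–Hochberg adjusted,
and a probe is a **differentially methylated probe (DMP)** when

&nbsp;&nbsp;&nbsp;&nbsp;|Δβ<sub>j</sub>| > 0.15 (strict) and q<sub>j</sub> ≤ 0.05,

hypermethylated when Δβ<sub>j</sub> > 0. Around the caller sit:

- a **probe filter cascade** (control probes, detection failures, low bead
  counts, non-CpG probes, sex chromosomes, polymorphic sites — each probe
  charged to the first rule that removes it);
- two transparent normalisation **surrogates**: a within-sample quantile
  mapping of type-II onto type-I probe distributions, and a per-probe
  M-scale location/scale batch standardisation (flagged as surrogates in
  every run summary);
- a **genomic interval engine** (0-based half-open): strand-aware promoter
  windows of 1500 bp (−1000/+500 around the TSS), CpG-island
  island/shore/shelf/open-sea tiers (2 kb / 2–4 kb), region classes with
  promoter > exon > intron > intergenic precedence;
- one-sided **hypergeometric enrichment** of DMPs in susceptibility loci,
  region classes and user-supplied gene sets, plus a two-sided Fisher exact
  test for small tables;
- **histopathology stratification**: per-feature paired reanalysis of the
  present and absent patient groups; a probe is *unique* to a stratum when
  it passes the joint DMP rule there but fails it in the counterpart;
- a **Pearson screen** of lesional β against maximum rete-peg length with
  tiers at |r| ≥ 0.4 and |r| ≥ 0.6 (both requiring p ≤ 0.05);
- a fully seeded **synthetic-study generator** that produces paired β
  matrices, probe annotation, susceptibility-like loci, histopathology
  tables and ground truth, so every stage is testable without any download.

Matrix-shaped stages are scikit-learn-style estimators
(`ProbeFilter`, `DesignBiasNormalizer`, `BatchAdjuster`,
`PairedDifferentialCaller`, `StratifiedDMPAnalysis`, `ReteLengthCorrelator`)
with `fit`/`transform`, `get_params`/`set_params` and underscore-suffixed
fitted attributes; module-level functions (`call_dmps`, `filter_probes`, …)
are thin wrappers over them.

## Worked example

```python
from methpair import (call_dmps, cluster_samples, correlate_rete_peg,
                      filter_probes, stratified_analysis)
from methpair.simulate import SimulationConfig, simulate_dataset, cohort_features

config = SimulationConfig(
    seed=42, n_probes=10_000,
    n_dmp_hyper=500, n_dmp_hypo=300, delta_beta_effect=0.25,
    feature_specs=cohort_features(n_unique_dmps=150),
    n_length_probes=30,
)
dataset = simulate_dataset(config)
matrix, report = filter_probes(dataset.matrix, dataset.annotation.probes)
print(f"probes: {report.n_input} -> {report.n_retained}")

result = call_dmps(matrix, delta_threshold=0.15, q_threshold=0.05)
print(f"DMPs: {result.n_dmp} ({result.n_hyper} hyper / {result.n_hypo} hypo)")

clust = cluster_samples(matrix, probe_ids=result.dmp_ids)
print(f"two-cluster purity (disease vs normal): {clust.purity}")

strat = stratified_analysis(matrix, dataset.histopathology, "munro_microabscess")
print(f"Munro-unique DMPs: {len(strat.unique_present)} present-only, "
      f"{len(strat.unique_absent)} absent-only, {len(strat.common)} common")

corr = correlate_rete_peg(matrix, dataset.histopathology)
print(f"rete-peg screen: {(corr['tier'] != 'none').sum()} correlated, "
      f"{(corr['tier'] == 'high').sum()} with |r| >= 0.6")
```

prints

```
probes: 10000 -> 9530
DMPs: 802 (502 hyper / 300 hypo)
two-cluster purity (disease vs normal): 1.0
Munro-unique DMPs: 156 present-only, 2 absent-only, 791 common
rete-peg screen: 201 correlated, 33 with |r| >= 0.6
```

The caller recovers the 800 spiked probes (plus two Munro-linked probes
strong enough to pass in the pooled analysis) with the correct hyper/hypo
split; the 150 feature-linked spikes land in the Munro present-only set with
a handful of borderline extras; the 30 length-tracking probes dominate the
|r| ≥ 0.6 tier. Complete-linkage clustering on the called DMPs separates
disease from normal samples perfectly, as expected at this effect size.

The same analysis runs from the shell:

```bash
methpair simulate --seed 42 --out study/        # write a synthetic study
methpair run --config config.yaml --seed 42     # end-to-end pipeline
```

where `config.yaml` either points at input files (β matrix + sample sheet,
annotation TSV, loci BED, transcript table, histopathology TSV) or contains
a `simulation:` block. Every run writes TSV/BED tables, a `run.log`, and a
`summary.json` that records thresholds, seeds and the surrogate normalisers
used.

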