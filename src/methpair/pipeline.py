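"""Configuration-driven end-to-end runner plus small validation-statistics
helpers (qPCR fold change, methylation-expression rank correlation).

A run executes: (optional) simulate -> probe filter -> design-bias
normalisation -> batch adjustment -> paired DMP calling -> promoter/locus
annotation -> enrichment -> per-feature stratified uniqueness -> rete-peg
correlation, writing every table as TSV/BED plus a JSON run summary. The
summary records the thresholds, the seed, and which stages ran surrogate
normalisers, so results are never mistaken for an array-vendor pipeline's.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .annotation import IntervalSet, PromoterSet, build_promoters, map_dmps_to_promoters, transcripts_from_tsv
from .containers import BetaMatrix, HistoFeatureTable, ProbeAnnotation
from .differential import call_dmps, cluster_samples, pca_samples
from .enrichment import locus_enrichment, region_class_enrichment
from .exceptions import ConfigurationError, MethpairError, ValidationError
from .histopath import correlate_rete_peg, stratified_analysis, MIN_STRATUM_PAIRS
from .preprocess import adjust_batch, filter_probes, normalize_design_bias
from .simulate import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Exactly one of ``input_dir`` (serialized study) or ``simulation``
    (generator config) must be set."""

    output_dir: str | Path = "methpair_out"
    input_dir: str | Path | None = None
    simulation: SimulationConfig | None = None
    delta_threshold: float = 0.15
    q_threshold: float = 0.05
    scale: str = "m"
    min_dmps_promoter: int = 1
    r_threshold: float = 0.4
    high_threshold: float = 0.6
    corr_p_threshold: float = 0.05
    sample_quota: float = 0.05
    features: tuple[str, ...] | None = None  # None -> all analyzable features

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of input_dir and simulation must be configured"
            )
        if not 0 < self.delta_threshold < 1:
            raise ConfigurationError("delta_threshold must lie in (0, 1)")
        for name in ("q_threshold", "corr_p_threshold", "sample_quota"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} outside [0, 1]")
        if not 0 <= self.r_threshold <= self.high_threshold <= 1:
            raise ConfigurationError("need 0 <= r_threshold <= high_threshold <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            from .simulate import FeatureSpec, cohort_features

            feats = sim.pop("feature_specs", None)
            if feats is not None:
                sim["feature_specs"] = tuple(FeatureSpec(**f) for f in feats)
            for key in ("length_range_um", "batch_offsets_m"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "region_mix" in sim:
                sim["region_mix"] = tuple((k, v) for k, v in sim["region_mix"].items())
            sim = SimulationConfig(**sim)
        if "features" in raw and raw["features"] is not None:
            raw["features"] = tuple(raw["features"])
        return cls(simulation=sim, **raw)


def _load_inputs(directory: Path):
    matrix = BetaMatrix.from_tsv(directory)
    annotation = ProbeAnnotation.from_tsv(directory / "annotation.tsv")
    loci = IntervalSet.from_bed(directory / "psors.bed", name="psors")
    transcripts = transcripts_from_tsv(directory / "transcripts.tsv")
    histo_path = directory / "histopathology.tsv"
    histo = HistoFeatureTable.from_tsv(histo_path) if histo_path.exists() else None
    return matrix, annotation, loci, transcripts, histo


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the JSON-serializable run summary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("methpair")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"stages": [], "surrogates": {}, "thresholds": {
        "delta_beta": config.delta_threshold,
        "q": config.q_threshold,
        "scale": config.scale,
        "r_tiers": [config.r_threshold, config.high_threshold],
        "min_dmps_promoter": config.min_dmps_promoter,
    }}
    stage = "configuration"
    try:
        # ------------------------------------------------------------ inputs
        if config.simulation is not None:
            stage = "simulate"
            dataset = simulate_dataset(config.simulation)
            write_dataset(dataset, out / "inputs")
            matrix, annotation = dataset.matrix, dataset.annotation.probes
            loci, transcripts = dataset.annotation.psors_loci, dataset.annotation.transcripts
            histo = dataset.histopathology
            summary["seed"] = config.simulation.seed
            summary["simulated"] = True
        else:
            stage = "load"
            matrix, annotation, loci, transcripts, histo = _load_inputs(Path(config.input_dir))
            summary["simulated"] = False
        summary["stages"].append(stage)
        summary["n_probes_input"] = matrix.n_probes
        summary["n_samples"] = matrix.n_samples

        # -------------------------------------------------------- preprocess
        stage = "filter"
        matrix, report = filter_probes(matrix, annotation, sample_quota=config.sample_quota)
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        summary["filter"] = {"n_input": report.n_input, "n_retained": report.n_retained,
                             "removed_by_rule": report.removed_by_rule}
        summary["stages"].append(stage)

        stage = "normalize"
        matrix = normalize_design_bias(matrix, annotation)
        summary["surrogates"]["normalizer"] = (
            "within-sample type-II->type-I quantile mapping (surrogate, not BMIQ)"
        )
        summary["stages"].append(stage)

        stage = "batch"
        matrix = adjust_batch(matrix)
        summary["surrogates"]["batch_adjuster"] = (
            "per-probe M-scale location/scale standardisation (surrogate, not ComBat)"
        )
        summary["stages"].append(stage)

        # ------------------------------------------------------ differential
        stage = "differential"
        result = call_dmps(matrix, delta_threshold=config.delta_threshold,
                           q_threshold=config.q_threshold, scale=config.scale)
        result.to_tsv(out / "differential.tsv")
        summary["differential"] = result.summary()
        with open(out / "dmp_ids.txt", "w") as fh:
            fh.write("\n".join(result.dmp_ids) + ("\n" if result.dmp_ids else ""))
        ann_table = annotation.table
        with open(out / "dmps.bed", "w") as fh:
            fh.write("# 0-based half-open (BED)\n")
            for pid in result.dmp_ids:
                row = ann_table.loc[pid]
                fh.write(f"{row['chrom']}\t{row['pos']}\t{row['pos'] + 1}\t{pid}\n")
        if result.n_dmp >= 2:
            clust = cluster_samples(matrix, probe_ids=result.dmp_ids)
            pca = pca_samples(matrix, probe_ids=result.dmp_ids)
            summary["clustering"] = {"purity": clust.purity, "degenerate": clust.degenerate}
            summary["pca_variance_fractions"] = [float(x) for x in pca.variance_fractions[:5]]
        summary["stages"].append(stage)

        # -------------------------------------------------------- annotation
        stage = "annotate"
        promoters: PromoterSet = build_promoters(transcripts)
        promoter_table = map_dmps_to_promoters(
            result, ann_table, promoters, min_dmps=config.min_dmps_promoter
        )
        promoter_table.to_csv(out / "differential_promoters.tsv", sep="\t")
        summary["promoters"] = {
            "n_with_dmp": int(len(promoter_table)),
            "n_selected": int(promoter_table["selected"].sum()) if len(promoter_table) else 0,
        }
        summary["stages"].append(stage)

        # -------------------------------------------------------- enrichment
        stage = "enrich"
        analyzable = ann_table.loc[matrix.probe_ids]
        locus_frame, overall = locus_enrichment(result.dmp_ids, analyzable, loci)
        locus_frame.to_csv(out / "locus_enrichment.tsv", sep="\t")
        summary["locus_enrichment"] = {
            "overall_k": overall.k, "overall_K": overall.K, "overall_p": overall.p_raw,
            "n_loci_nominal": int((locus_frame["testable"] & (locus_frame["p_raw"] <= 0.05)).sum()),
        }
        if "region_class" in analyzable.columns:
            region_frame = region_class_enrichment(result.dmp_ids, analyzable["region_class"])
            region_frame.to_csv(out / "region_class_enrichment.tsv", sep="\t")
        summary["stages"].append(stage)

        # ---------------------------------------------------- histopathology
        if histo is not None:
            stage = "stratify"
            strat_summaries = {}
            features = config.features or histo.feature_names
            for feature in features:
                try:
                    res = stratified_analysis(
                        matrix, histo, feature,
                        delta_threshold=config.delta_threshold,
                        q_threshold=config.q_threshold, scale=config.scale,
                    )
                except ValidationError as exc:
                    logger.warning("skipping feature %s: %s", feature, exc)
                    strat_summaries[feature] = {"skipped": str(exc)}
                    continue
                strat_summaries[feature] = {
                    "n_unique_present": len(res.unique_present),
                    "n_unique_absent": len(res.unique_absent),
                    "n_common": len(res.common),
                }
                for label, probe_set in (
                    ("unique_present", res.unique_present),
                    ("unique_absent", res.unique_absent),
                    ("common", res.common),
                ):
                    with open(out / f"{feature}_{label}.txt", "w") as fh:
                        fh.write("\n".join(sorted(probe_set)) + ("\n" if probe_set else ""))
            summary["stratified"] = strat_summaries
            summary["stages"].append(stage)

            stage = "correlate"
            if histo.rete_peg_length_um.notna().sum() >= 4 and result.n_dmp:
                corr = correlate_rete_peg(
                    matrix, histo, probe_ids=result.dmp_ids,
                    p_threshold=config.corr_p_threshold,
                    r_threshold=config.r_threshold,
                    high_threshold=config.high_threshold,
                )
                corr.to_csv(out / "rete_peg_correlation.tsv", sep="\t", index_label="probe_id")
                summary["rete_correlation"] = {
                    "n_correlated": int((corr["tier"] != "none").sum()),
                    "n_high": int((corr["tier"] == "high").sum()),
                }
                summary["stages"].append(stage)
    except Exception as exc:
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_json_default)
        root.removeHandler(handler)
        handler.close()
        raise MethpairError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    root.removeHandler(handler)
    handler.close()
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ------------------------------------------------------- validation statistics
@dataclass(frozen=True)
class QPCRRecord:
    """Threshold cycles for a target/reference gene pair in a test condition
    and a calibrator condition."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_calibrator: float
    ct_ref_calibrator: float

    def __post_init__(self) -> None:
        for name in ("ct_target_test", "ct_ref_test", "ct_target_calibrator", "ct_ref_calibrator"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


def ddct_fold_change(record: QPCRRecord) -> float:
    """Relative quantification: fold = 2^-ΔΔCt with
    ΔΔCt = (Ct_target - Ct_ref)_test - (Ct_target - Ct_ref)_calibrator."""
    ddct = (record.ct_target_test - record.ct_ref_test) - (
        record.ct_target_calibrator - record.ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))


def spearman_meth_expr(promoter_beta_means, expression_fold_changes) -> tuple[float, float]:
    """Spearman rank correlation (tie-aware) between promoter methylation and
    expression fold change; two-sided p. Constant input is flagged as an error."""
    x = np.asarray(promoter_beta_means, dtype=float)
    y = np.asarray(expression_fold_changes, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
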