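"""Probe filtering and scale/normalisation transforms.

The filter cascade mirrors standard 450k practice: control probes, probes
failing detection in too many samples, probes with low bead representation,
non-CpG probes, sex-chromosome probes and probes overlapping polymorphic
sites are removed, in that order, and each probe is charged to the first
rule that removes it.

Two deliberately simple, fully specified surrogates replace the usual
array normalisers:

* :class:`DesignBiasNormalizer` — a within-sample quantile mapping of
  type-II probe β values onto the empirical distribution of that sample's
  type-I probes (a BMIQ-style design-bias correction without the
  beta-mixture machinery);
* :class:`BatchAdjuster` — a per-probe location/scale standardisation of
  each batch on the M scale, rescaled to the probe's pooled moments (a
  ComBat-style adjustment without empirical-Bayes shrinkage).

Both are flagged as surrogates in logs and run summaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import BetaMatrix, ProbeAnnotation
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: logit clamp; keeps M finite with negligible distortion of interior values
LOGIT_EPS = 1e-6


# --------------------------------------------------------------------- scales
def beta_to_m(beta):
    """M = log2(β/(1−β)) with β clamped to [ε, 1−ε], ε = 1e-6."""
    b = np.clip(np.asarray(beta, dtype=float), LOGIT_EPS, 1.0 - LOGIT_EPS)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse logit2: β = 2^M / (1 + 2^M), numerically stable for large |M|."""
    m = np.asarray(m, dtype=float)
    out = np.empty_like(m)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    out[~pos] = np.exp2(m[~pos]) / (1.0 + np.exp2(m[~pos]))
    return out


# --------------------------------------------------------------------- filter
@dataclass
class FilterReport:
    """Per-rule toll of the sequential probe-filter cascade."""

    n_input: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.removed_by_rule.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": n} for r, n in self.removed_by_rule.items()]
        rows.append({"rule": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)


#: cascade order; each probe is counted at the first rule that removes it
FILTER_RULES = ("control", "detection", "bead", "non_cpg", "sex_chrom", "polymorphic")


class ProbeFilter(BaseEstimator, TransformerMixin):
    """Sequential probe-removal cascade.

    Parameters
    ----------
    annotation
        Probe annotation covering every probe in the matrix.
    sample_quota
        Failure quota for the detection and bead rules: a probe is removed
        if it fails in *more than* this fraction of samples (strict ``>``;
        the quota is exposed because ">5%" vs "≥5%" is a convention choice).
    """

    def __init__(self, annotation: ProbeAnnotation | None = None, sample_quota: float = 0.05):
        self.annotation = annotation
        self.sample_quota = sample_quota

    def fit(self, X: BetaMatrix, y=None) -> "ProbeFilter":
        if self.annotation is None:
            raise ValidationError("ProbeFilter requires an annotation")
        ann = self.annotation.require(X.probe_ids)

        n_samples = X.n_samples
        removal = {}

        def fail_fraction(grid: pd.DataFrame | None) -> pd.Series:
            if grid is None:
                return pd.Series(0.0, index=X.probe_ids)
            return grid.sum(axis=1) / n_samples

        candidates = {
            "control": ann["is_control"].astype(bool),
            "detection": fail_fraction(X.detection_fail) > self.sample_quota,
            "bead": fail_fraction(X.low_bead) > self.sample_quota,
            "non_cpg": ~ann["is_cpg"].astype(bool),
            "sex_chrom": ann["chrom"].isin({"chrX", "chrY", "X", "Y"}),
            "polymorphic": ann["is_polymorphic"].astype(bool),
        }
        already = pd.Series(False, index=X.probe_ids)
        for rule in FILTER_RULES:
            hit = candidates[rule] & ~already
            removal[rule] = hit
            already = already | hit

        self.removed_by_rule_ = {rule: int(removal[rule].sum()) for rule in FILTER_RULES}
        self.keep_mask_ = ~already
        self.report_ = FilterReport(n_input=X.n_probes, removed_by_rule=dict(self.removed_by_rule_))
        logger.info(
            "probe filter: %d -> %d (%s)",
            X.n_probes,
            self.report_.n_retained,
            ", ".join(f"{r}={n}" for r, n in self.removed_by_rule_.items()),
        )
        return self

    def transform(self, X: BetaMatrix) -> BetaMatrix:
        if not hasattr(self, "keep_mask_"):
            raise ValidationError("ProbeFilter is not fitted")
        keep = self.keep_mask_.reindex(X.probe_ids).fillna(False)
        return X.subset_probes(X.probe_ids[keep.to_numpy(dtype=bool)])


def filter_probes(
    matrix: BetaMatrix, annotation: ProbeAnnotation, sample_quota: float = 0.05
) -> tuple[BetaMatrix, FilterReport]:
    """Functional wrapper around :class:`ProbeFilter`."""
    flt = ProbeFilter(annotation=annotation, sample_quota=sample_quota).fit(matrix)
    return flt.transform(matrix), flt.report_


# ---------------------------------------------------------- design-bias (BMIQ surrogate)
class DesignBiasNormalizer(BaseEstimator, TransformerMixin):
    """Quantile-map type-II probe β values onto each sample's type-I distribution.

    A stateless per-sample transform (fit only validates); type-I values are
    left untouched, and the mapping is monotone so within-sample type-II
    rankings are preserved.
    """

    MIN_TYPE1 = 50

    def __init__(self, annotation: ProbeAnnotation | None = None):
        self.annotation = annotation

    def fit(self, X: BetaMatrix, y=None) -> "DesignBiasNormalizer":
        if self.annotation is None:
            raise ValidationError("DesignBiasNormalizer requires an annotation")
        ann = self.annotation.require(X.probe_ids)
        self.is_type1_ = (ann["probe_type"] == "I").to_numpy()
        return self

    def transform(self, X: BetaMatrix) -> BetaMatrix:
        if not hasattr(self, "is_type1_"):
            raise ValidationError("DesignBiasNormalizer is not fitted")
        vals = X.values.to_numpy(dtype=float).copy()
        t1, t2 = self.is_type1_, ~self.is_type1_
        if not t2.any():
            logger.info("design-bias surrogate: all probes type I, identity transform")
            return X.copy()
        for j, sample in enumerate(X.values.columns):
            ref = vals[t1, j]
            ref = ref[~np.isnan(ref)]
            if ref.size < self.MIN_TYPE1:
                raise ValidationError(
                    f"sample {sample!r} has only {ref.size} type-I probes "
                    f"(< {self.MIN_TYPE1}); refusing to quantile-map"
                )
            col = vals[t2, j]
            ok = ~np.isnan(col)
            if ok.sum() == 0:
                continue
            x = col[ok]
            # mid-rank empirical quantiles of the type-II values, mapped
            # through the type-I empirical quantile function
            order = np.argsort(x, kind="stable")
            ranks = np.empty(x.size)
            ranks[order] = np.arange(1, x.size + 1)
            q = (ranks - 0.5) / x.size
            mapped = np.quantile(ref, q)
            col[ok] = mapped
            vals[np.flatnonzero(t2), j] = col
        out = X.copy()
        out.values = pd.DataFrame(vals, index=X.values.index, columns=X.values.columns)
        logger.info("design-bias surrogate applied (quantile mapping, not BMIQ)")
        return out


def normalize_design_bias(matrix: BetaMatrix, annotation: ProbeAnnotation) -> BetaMatrix:
    """Functional wrapper around :class:`DesignBiasNormalizer`."""
    return DesignBiasNormalizer(annotation=annotation).fit(matrix).transform(matrix)


# ----------------------------------------------------------- batch (ComBat surrogate)
class BatchAdjuster(BaseEstimator, TransformerMixin):
    """Per-probe location/scale batch standardisation on the M scale.

    For each probe, every batch's values are z-scored against that batch's
    mean/SD and rescaled to the probe's pooled mean/SD, then mapped back to
    β. Each probe's pooled mean is preserved exactly (up to float error).
    """

    def fit(self, X: BetaMatrix, y=None) -> "BatchAdjuster":
        counts = X.samples["batch"].value_counts()
        singletons = counts[counts < 2]
        if len(singletons):
            raise ValidationError(
                f"batch(es) with a single sample cannot be adjusted: {list(singletons.index)}"
            )
        self.batches_ = list(counts.index)
        return self

    def transform(self, X: BetaMatrix) -> BetaMatrix:
        if not hasattr(self, "batches_"):
            raise ValidationError("BatchAdjuster is not fitted")
        m = beta_to_m(X.values.to_numpy(dtype=float))
        pooled_mean = np.nanmean(m, axis=1, keepdims=True)
        pooled_sd = np.nanstd(m, axis=1, keepdims=True, ddof=0)
        out = m.copy()
        batch_labels = X.samples["batch"].to_numpy()
        for batch in self.batches_:
            cols = batch_labels == batch
            sub = m[:, cols]
            b_mean = np.nanmean(sub, axis=1, keepdims=True)
            b_sd = np.nanstd(sub, axis=1, keepdims=True, ddof=0)
            scale = np.where(b_sd > 0, pooled_sd / np.where(b_sd > 0, b_sd, 1.0), 1.0)
            out[:, cols] = (sub - b_mean) * scale + pooled_mean
        # degenerate probes (zero pooled spread) are left unchanged
        flat = pooled_sd[:, 0] == 0
        out[flat] = m[flat]
        adjusted = X.copy()
        adjusted.values = pd.DataFrame(
            m_to_beta(out), index=X.values.index, columns=X.values.columns
        )
        logger.info(
            "batch surrogate applied (M-scale location/scale, not ComBat) over batches %s",
            self.batches_,
        )
        return adjusted


def adjust_batch(matrix: BetaMatrix) -> BetaMatrix:
    """Functional wrapper around :class:`BatchAdjuster`."""
    return BatchAdjuster().fit(matrix).transform(matrix)
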