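"""Histopathology-feature-stratified differential methylation.

For each binary feature (e.g. Munro's microabscess) the cohort is split
into feature-present and feature-absent patients (missing values drop the
patient for that feature only), a separate paired DMP analysis is run in
each stratum, and probes are classed as *unique* to a stratum when they
meet the joint |Δβ|/FDR rule there but fail it in the counterpart. A
correlation screen relates lesional β to the continuous rete-peg length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import BetaMatrix, HistoFeatureTable, DISEASE
from .differential import DifferentialResult, PairedDifferentialCaller
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

MIN_STRATUM_PAIRS = 3


# ------------------------------------------------------------------ stratify
def stratify(
    matrix: BetaMatrix, histo: HistoFeatureTable, feature: str
) -> tuple[BetaMatrix, BetaMatrix]:
    """Split the paired matrix into feature-present and feature-absent strata.

    Patients with a missing feature value are excluded; both strata retain
    full disease/normal pairs. Fewer than 3 pairs in either stratum is
    refused.
    """
    matrix.validate_paired()
    present, absent = histo.feature_groups(feature)
    known = set(matrix.patients)
    present = [p for p in present if p in known]
    absent = [p for p in absent if p in known]
    if len(present) < MIN_STRATUM_PAIRS or len(absent) < MIN_STRATUM_PAIRS:
        raise ValidationError(
            f"feature {feature!r}: strata of {len(present)}/{len(absent)} pairs "
            f"(need >= {MIN_STRATUM_PAIRS} each)"
        )
    return matrix.subset_patients(present), matrix.subset_patients(absent)


# ---------------------------------------------------------------- uniqueness
def unique_dmps(
    result_a: DifferentialResult,
    result_b: DifferentialResult,
    counterpart_rule: str = "joint",
) -> tuple[set[str], set[str], set[str]]:
    """(unique_A, unique_B, common) DMP sets over a shared probe universe.

    ``counterpart_rule='joint'`` (default): "not significant in the
    counterpart" means failing the joint |Δβ|/FDR DMP rule there.
    ``counterpart_rule='padj'`` is the stricter alternative: the counterpart
    must additionally have adjusted p > the q threshold.
    """
    if result_a.probe_universe != result_b.probe_universe:
        raise ValidationError("stratified results cover different probe universes")
    dmp_a, dmp_b = set(result_a.dmp_ids), set(result_b.dmp_ids)
    common = dmp_a & dmp_b
    unique_a, unique_b = dmp_a - dmp_b, dmp_b - dmp_a
    if counterpart_rule == "padj":
        pa, pb = result_a.table["p_adj"], result_b.table["p_adj"]
        unique_a = {p for p in unique_a if not (pb.loc[p] <= result_b.q_threshold)}
        unique_b = {p for p in unique_b if not (pa.loc[p] <= result_a.q_threshold)}
    elif counterpart_rule != "joint":
        raise ValidationError(f"unknown counterpart rule {counterpart_rule!r}")
    return unique_a, unique_b, common


@dataclass
class StratifiedResult:
    """Per-feature stratified analysis with its unique/common probe sets."""

    feature: str
    present_result: DifferentialResult
    absent_result: DifferentialResult
    unique_present: set[str]
    unique_absent: set[str]
    common: set[str]

    def __post_init__(self) -> None:
        # structural invariants of the uniqueness decomposition; under the
        # stricter 'padj' counterpart rule the unions are subsets rather
        # than equalities, so subset relations are what is asserted
        present_dmps = set(self.present_result.dmp_ids)
        absent_dmps = set(self.absent_result.dmp_ids)
        if self.unique_present & self.unique_absent:
            raise ValidationError("unique sets of the two strata overlap")
        if not (self.common <= present_dmps and self.common <= absent_dmps):
            raise ValidationError("common set is not a subset of both strata's DMPs")
        if not (self.unique_present | self.common) <= present_dmps:
            raise ValidationError("present-stratum decomposition inconsistent")
        if not (self.unique_absent | self.common) <= absent_dmps:
            raise ValidationError("absent-stratum decomposition inconsistent")


class StratifiedDMPAnalysis(BaseEstimator):
    """Estimator interface: stratify on a feature and call DMPs per stratum.

    DMP thresholds mirror :class:`~methpair.differential.PairedDifferentialCaller`.
    """

    def __init__(
        self,
        feature: str | None = None,
        delta_threshold: float = 0.15,
        q_threshold: float = 0.05,
        scale: str = "m",
        counterpart_rule: str = "joint",
    ):
        self.feature = feature
        self.delta_threshold = delta_threshold
        self.q_threshold = q_threshold
        self.scale = scale
        self.counterpart_rule = counterpart_rule

    def fit(self, X: BetaMatrix, y: HistoFeatureTable = None) -> "StratifiedDMPAnalysis":
        if self.feature is None or y is None:
            raise ValidationError("StratifiedDMPAnalysis needs a feature and a histo table")
        present, absent = stratify(X, y, self.feature)
        caller = lambda m: PairedDifferentialCaller(
            delta_threshold=self.delta_threshold,
            q_threshold=self.q_threshold,
            scale=self.scale,
        ).fit(m).result_
        res_p, res_a = caller(present), caller(absent)
        up, ua, common = unique_dmps(res_p, res_a, counterpart_rule=self.counterpart_rule)
        self.result_ = StratifiedResult(
            feature=self.feature, present_result=res_p, absent_result=res_a,
            unique_present=up, unique_absent=ua, common=common,
        )
        logger.info(
            "feature %s: %d unique-present, %d unique-absent, %d common DMPs",
            self.feature, len(up), len(ua), len(common),
        )
        return self


def stratified_analysis(
    matrix: BetaMatrix,
    histo: HistoFeatureTable,
    feature: str,
    delta_threshold: float = 0.15,
    q_threshold: float = 0.05,
    scale: str = "m",
    counterpart_rule: str = "joint",
) -> StratifiedResult:
    """Functional wrapper around :class:`StratifiedDMPAnalysis`."""
    est = StratifiedDMPAnalysis(
        feature=feature, delta_threshold=delta_threshold, q_threshold=q_threshold,
        scale=scale, counterpart_rule=counterpart_rule,
    ).fit(matrix, histo)
    return est.result_


# -------------------------------------------------------- cross-feature table
def cross_feature_overlap(results: list[StratifiedResult]) -> pd.DataFrame:
    """Pairwise and full intersections of the unique-present DMP sets.

    Each row reports an intersection's size and its direction composition
    (counts of hyper/hypo probes, judged by Δβ sign in the present stratum
    of the first feature involved).
    """
    if len(results) < 2:
        raise ValidationError("cross-feature overlap needs >= 2 stratified results")
    rows = []

    def direction_counts(probes: set[str], ref: StratifiedResult) -> tuple[int, int]:
        if not probes:
            return 0, 0
        d = ref.present_result.table["delta_beta"].loc[sorted(probes)]
        return int((d > 0).sum()), int((d < 0).sum())

    for i, a in enumerate(results):
        for b in results[i + 1 :]:
            inter = a.unique_present & b.unique_present
            hyper, hypo = direction_counts(inter, a)
            rows.append(
                {"features": f"{a.feature} & {b.feature}", "n": len(inter),
                 "n_hyper": hyper, "n_hypo": hypo,
                 "probes": ",".join(sorted(inter))}
            )
    full = set.intersection(*(r.unique_present for r in results))
    hyper, hypo = direction_counts(full, results[0])
    rows.append(
        {"features": " & ".join(r.feature for r in results), "n": len(full),
         "n_hyper": hyper, "n_hypo": hypo, "probes": ",".join(sorted(full))}
    )
    return pd.DataFrame(rows).set_index("features")


# --------------------------------------------------------- length correlation
class ReteLengthCorrelator(BaseEstimator):
    """Pearson screen of lesional β against rete-peg length.

    Per probe: r and two-sided p of disease-tissue β vs per-patient length.
    A probe enters the ``correlated`` tier at p <= p_threshold and
    |r| >= r_threshold, and the ``high`` tier at |r| >= high_threshold
    (high ⊆ correlated). Constant β or length vectors are excluded with a
    flag. With ``include_normal=True`` the paired β difference replaces the
    lesional β.
    """

    def __init__(
        self,
        p_threshold: float = 0.05,
        r_threshold: float = 0.4,
        high_threshold: float = 0.6,
        include_normal: bool = False,
    ):
        self.p_threshold = p_threshold
        self.r_threshold = r_threshold
        self.high_threshold = high_threshold
        self.include_normal = include_normal

    def fit(
        self, X: BetaMatrix, y: HistoFeatureTable = None, probe_ids=None
    ) -> "ReteLengthCorrelator":
        if y is None:
            raise ValidationError("ReteLengthCorrelator needs a histopathology table")
        sub = X if probe_ids is None else X.subset_probes(probe_ids)
        disease, normal = sub.paired_views()
        profile = disease - normal if self.include_normal else disease
        lengths = y.rete_peg_length_um.reindex(profile.columns)
        ok = lengths.notna()
        if ok.sum() < 4:
            raise ValidationError("need >= 4 patients with a rete-peg length")
        prof = profile.loc[:, ok.to_numpy()].to_numpy(dtype=float)
        L = lengths[ok].to_numpy(dtype=float)
        n = L.size

        Lc = L - L.mean()
        var_l = (Lc**2).sum()
        excluded = np.zeros(prof.shape[0], dtype=bool)
        if var_l == 0:
            excluded[:] = True
        pc = prof - prof.mean(axis=1, keepdims=True)
        var_p = (pc**2).sum(axis=1)
        excluded |= var_p == 0
        r = np.full(prof.shape[0], np.nan)
        valid = ~excluded
        r[valid] = (pc[valid] @ Lc) / np.sqrt(var_p[valid] * var_l)
        r = np.clip(r, -1.0, 1.0)
        p = np.full_like(r, np.nan)
        with np.errstate(divide="ignore"):
            t = r[valid] * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r[valid] ** 2))
        p[valid] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

        significant = valid & (p <= self.p_threshold)
        tier = np.where(
            significant & (np.abs(r) >= self.high_threshold), "high",
            np.where(significant & (np.abs(r) >= self.r_threshold), "correlated", "none"),
        )
        self.records_ = pd.DataFrame(
            {"r": r, "p_raw": p, "tier": tier, "excluded": excluded, "n": n},
            index=profile.index,
        )
        self.n_correlated_ = int((self.records_["tier"] != "none").sum())
        self.n_high_ = int((self.records_["tier"] == "high").sum())
        return self


def correlate_rete_peg(
    matrix: BetaMatrix,
    histo: HistoFeatureTable,
    probe_ids=None,
    p_threshold: float = 0.05,
    r_threshold: float = 0.4,
    high_threshold: float = 0.6,
) -> pd.DataFrame:
    """Functional wrapper around :class:`ReteLengthCorrelator`."""
    est = ReteLengthCorrelator(
        p_threshold=p_threshold, r_threshold=r_threshold, high_threshold=high_threshold
    ).fit(matrix, histo, probe_ids=probe_ids)
    return est.records_


# ------------------------------------------------------------------ top-k sets
def top_unique_for_pca(
    unique_set: set[str], result: DifferentialResult, k: int = 100
) -> list[str]:
    """Rank a unique-DMP set for PCA: ascending adjusted p, ties broken by
    descending |Δβ|, then lexicographic probe ID; return the top min(k, size)."""
    if not unique_set:
        raise ValidationError("unique probe set is empty")
    sub = result.table.loc[sorted(unique_set)]
    ranked = sub.assign(abs_delta=sub["delta_beta"].abs()).sort_values(
        ["p_adj", "abs_delta"], ascending=[True, False], kind="stable"
    )
    # pandas stable sort keeps the lexicographic index order within full ties
    return list(ranked.index[: min(k, len(ranked))])
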