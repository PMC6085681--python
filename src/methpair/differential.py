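"""Paired differential methylation.

The effect size is always reported on the β scale (Δβ = mean over patients
of disease β − normal β), while the paired one-sample t-test defaults to the
variance-stabilised M scale. A probe is called a DMP when |Δβ| exceeds the
effect threshold (strict ``>``) *and* its BH-adjusted p-value is at or below
the FDR threshold (``<=``). Plain paired t is the only test offered — no
variance moderation — which is a deliberate simplification.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix
from .exceptions import ValidationError
from .preprocess import beta_to_m

logger = logging.getLogger(__name__)

HYPER = "hyper"
HYPO = "hypo"


# ------------------------------------------------------------------ building blocks
def paired_delta_beta(matrix: BetaMatrix, min_pairs: int = 3) -> pd.Series:
    """Per-probe mean paired difference of β (disease − normal).

    Patients with a missing value at a probe are dropped for that probe;
    probes with fewer than ``min_pairs`` complete pairs get NaN.
    """
    disease, normal = matrix.paired_views()
    diff = disease.to_numpy(dtype=float) - normal.to_numpy(dtype=float)
    n = np.sum(~np.isnan(diff), axis=1)
    delta = np.nansum(np.where(np.isnan(diff), 0.0, diff), axis=1) / np.maximum(n, 1)
    delta[n < min_pairs] = np.nan
    return pd.Series(delta, index=matrix.probe_ids, name="delta_beta")


def paired_test(matrix: BetaMatrix, scale: str = "m", min_pairs: int = 3) -> pd.DataFrame:
    """Paired one-sample t-test per probe on the chosen scale (``m`` or ``beta``).

    Returns a frame with columns statistic, p_raw, n_pairs and degenerate
    (True when the per-patient differences have zero variance, in which case
    the p-value is undefined and the probe must never be called a DMP).
    """
    if scale not in {"m", "beta"}:
        raise ValidationError(f"unknown test scale {scale!r}")
    disease, normal = matrix.paired_views()
    d_vals = disease.to_numpy(dtype=float)
    n_vals = normal.to_numpy(dtype=float)
    if scale == "m":
        d_vals, n_vals = beta_to_m(d_vals), beta_to_m(n_vals)
    diff = d_vals - n_vals
    valid = ~np.isnan(diff)
    n = valid.sum(axis=1)
    filled = np.where(valid, diff, 0.0)
    mean = filled.sum(axis=1) / np.maximum(n, 1)
    ss = np.where(valid, (diff - mean[:, None]) ** 2, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
    tested = n >= min_pairs
    degenerate = tested & (sd == 0)
    ok = tested & (sd > 0)
    t = np.full(len(n), np.nan)
    p = np.full(len(n), np.nan)
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n[ok]))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n[ok] - 1)
    return pd.DataFrame(
        {"statistic": t, "p_raw": p, "n_pairs": n, "degenerate": degenerate},
        index=matrix.probe_ids,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved, capped at 1.

    NaN entries (untested probes) are passed through without affecting the
    adjustment of the finite entries.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


# ------------------------------------------------------------------ DMP calling
@dataclass
class DifferentialResult:
    """Per-probe differential records plus the thresholds that produced them.

    ``table`` is indexed by probe ID with columns delta_beta, statistic,
    p_raw, p_adj, n_pairs, degenerate, is_dmp, direction.
    """

    table: pd.DataFrame
    delta_threshold: float
    q_threshold: float
    scale: str

    @property
    def n_tested(self) -> int:
        return int(self.table["p_raw"].notna().sum())

    @property
    def n_dmp(self) -> int:
        return int(self.table["is_dmp"].sum())

    @property
    def n_hyper(self) -> int:
        return int((self.table["direction"] == HYPER).sum())

    @property
    def n_hypo(self) -> int:
        return int((self.table["direction"] == HYPO).sum())

    @property
    def dmp_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_dmp"]])

    @property
    def probe_universe(self) -> frozenset:
        return frozenset(self.table.index)

    def summary(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_dmp": self.n_dmp,
            "n_hyper": self.n_hyper,
            "n_hypo": self.n_hypo,
            "delta_threshold": self.delta_threshold,
            "q_threshold": self.q_threshold,
            "scale": self.scale,
        }

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="probe_id")


class PairedDifferentialCaller(BaseEstimator):
    """Estimator interface to the paired DMP caller.

    Parameters
    ----------
    delta_threshold
        β-scale effect floor; a DMP needs |Δβ| strictly greater than this.
    q_threshold
        BH-adjusted p ceiling (inclusive).
    scale
        Scale for the paired t-test (``m`` default, or ``beta``); the Δβ
        threshold is always evaluated on the β scale.
    min_pairs
        Minimum complete pairs for a probe to be tested.
    """

    def __init__(
        self,
        delta_threshold: float = 0.15,
        q_threshold: float = 0.05,
        scale: str = "m",
        min_pairs: int = 3,
    ):
        self.delta_threshold = delta_threshold
        self.q_threshold = q_threshold
        self.scale = scale
        self.min_pairs = min_pairs

    def fit(self, X: BetaMatrix, y=None) -> "PairedDifferentialCaller":
        delta = paired_delta_beta(X, min_pairs=self.min_pairs)
        tests = paired_test(X, scale=self.scale, min_pairs=self.min_pairs)
        p_adj = bh_adjust(tests["p_raw"].to_numpy())
        table = tests.copy()
        table.insert(0, "delta_beta", delta)
        table["p_adj"] = p_adj
        is_dmp = (
            (np.abs(table["delta_beta"]) > self.delta_threshold)
            & (table["p_adj"] <= self.q_threshold)
            & ~table["degenerate"]
        ).fillna(False)
        direction = pd.Series(pd.NA, index=table.index, dtype=object)
        direction[is_dmp & (table["delta_beta"] > 0)] = HYPER
        direction[is_dmp & (table["delta_beta"] < 0)] = HYPO
        table["is_dmp"] = is_dmp.astype(bool)
        table["direction"] = direction
        self.result_ = DifferentialResult(
            table=table,
            delta_threshold=self.delta_threshold,
            q_threshold=self.q_threshold,
            scale=self.scale,
        )
        self.n_dmp_ = self.result_.n_dmp
        self.n_hyper_ = self.result_.n_hyper
        self.n_hypo_ = self.result_.n_hypo
        logger.info(
            "DMP calling: %d tested, %d DMPs (%d hyper / %d hypo)",
            self.result_.n_tested, self.n_dmp_, self.n_hyper_, self.n_hypo_,
        )
        return self


def call_dmps(
    matrix: BetaMatrix,
    delta_threshold: float = 0.15,
    q_threshold: float = 0.05,
    scale: str = "m",
    min_pairs: int = 3,
) -> DifferentialResult:
    """Functional wrapper around :class:`PairedDifferentialCaller`."""
    caller = PairedDifferentialCaller(
        delta_threshold=delta_threshold, q_threshold=q_threshold,
        scale=scale, min_pairs=min_pairs,
    ).fit(matrix)
    return caller.result_


# ------------------------------------------------------------------ diagnostics
@dataclass
class ClusterResult:
    """Complete-linkage clustering of sample β profiles."""

    linkage: np.ndarray
    labels: pd.Series              # two-cluster partition, by sample
    purity: float | None           # vs tissue labels, when available
    degenerate: bool = False


def cluster_samples(matrix: BetaMatrix, probe_ids=None) -> ClusterResult:
    """Euclidean-distance, complete-linkage clustering of samples.

    ``probe_ids`` restricts the profile to a probe set (e.g. called DMPs).
    Cutting the dendrogram at two clusters yields a partition; purity is the
    best-matching fraction of samples grouped consistently with their tissue
    label. A constant matrix is reported as a degenerate partition.
    """
    sub = matrix if probe_ids is None else matrix.subset_probes(probe_ids)
    if sub.n_samples < 2 or sub.n_probes < 1:
        raise ValidationError("clustering needs >= 2 samples and >= 1 probe")
    profiles = sub.values.to_numpy(dtype=float).T
    dists = pdist(profiles, metric="euclidean")
    degenerate = bool(np.all(dists == 0))
    Z = hierarchy.linkage(profiles, method="complete", metric="euclidean")
    assignment = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    labels = pd.Series(assignment, index=sub.values.columns, name="cluster")
    tissue = sub.samples["tissue"]
    purity = None
    if tissue.nunique() == 2:
        match = (labels.to_numpy() == 1) == (tissue.to_numpy() == tissue.unique()[0])
        purity = float(max(match.mean(), 1 - match.mean()))
    return ClusterResult(linkage=Z, labels=labels, purity=purity, degenerate=degenerate)


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    variance_fractions: np.ndarray  # sums to 1


def pca_samples(matrix: BetaMatrix, probe_ids=None) -> PCAResult:
    """Centered PCA over samples (probes as variables) via SVD.

    Variance fractions are normalised over all non-trivial components and
    sum to 1.
    """
    sub = matrix if probe_ids is None else matrix.subset_probes(probe_ids)
    if sub.n_samples < 2:
        raise ValidationError("PCA needs >= 2 samples")
    if sub.n_probes < 1:
        raise ValidationError("PCA needs >= 1 probe")
    X = sub.values.to_numpy(dtype=float).T
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1])  # centering removes one dimension
    s = s[:k]
    scores = U[:, :k] * s
    var = s**2
    total = var.sum()
    fractions = var / total if total > 0 else np.full(k, np.nan)
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=sub.values.columns,
            columns=[f"PC{i+1}" for i in range(k)],
        ),
        variance_fractions=fractions,
    )
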