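"""Over-representation statistics.

All enrichment tests are one-sided hypergeometric upper tails (is the
selected set over-represented in a category, relative to the analyzable
background?) with BH adjustment across categories. Under-representation
is available behind ``alternative='under'`` where exposed. The background
is always the post-filter analyzable probe/gene universe, not the full
array.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import IntervalSet, overlap
from .differential import bh_adjust
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    """One category's over-representation record.

    N: background size; K: background members in the category; n: selected
    set size; k: selected members in the category; fold = (k/n)/(K/N).
    """

    name: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_adj: float = np.nan
    testable: bool = True

    @property
    def fold(self) -> float:
        if self.n == 0 or self.K == 0:
            return np.nan
        return (self.k / self.n) / (self.K / self.N)


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    Bounds: 0 <= K <= N, 0 <= n <= N, max(0, n+K-N) <= k <= min(n, K).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValidationError(f"count k={k} outside feasible range for N={N}, K={K}, n={n}")
    # sf(k-1) = P(X >= k); scipy computes the tail stably
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _records_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "name": r.name, "N": r.N, "K": r.K, "n": r.n, "k": r.k,
            "fold": r.fold, "p_raw": r.p_raw, "p_adj": r.p_adj,
            "testable": r.testable,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("name")


def _adjust(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    testable = [r for r in records if r.testable]
    if testable:
        adj = bh_adjust([r.p_raw for r in testable])
        for r, a in zip(testable, adj):
            r.p_adj = float(a)
    return records


def _category_records(
    categories: pd.Series, selected: pd.Series, alternative: str = "over"
) -> list[EnrichmentRecord]:
    """Shared core: categorical label per background member + selection mask."""
    N = len(categories)
    n = int(selected.sum())
    records = []
    for name, members in categories.groupby(categories, sort=True):
        K = len(members)
        k = int(selected.loc[members.index].sum())
        if K == 0:
            records.append(EnrichmentRecord(str(name), N, 0, n, 0, 1.0, testable=False))
            continue
        if alternative == "over":
            p = hypergeom_upper(N, K, n, k)
        else:
            p = float(stats.hypergeom.cdf(k, N, K, n))
        records.append(EnrichmentRecord(str(name), N, K, n, k, p))
    return _adjust(records)


# -------------------------------------------------------------- locus (PSORS)
def locus_enrichment(
    dmp_probes,
    probe_table: pd.DataFrame,
    loci: IntervalSet,
    alternative: str = "over",
) -> tuple[pd.DataFrame, EnrichmentRecord]:
    """Per-locus DMP over-representation plus a pooled all-loci record.

    ``probe_table`` holds the analyzable background (chrom/pos per probe);
    ``dmp_probes`` must be a subset of it. Loci with zero background probes
    are emitted with K=0, p=1 and flagged untestable. BH runs across loci.
    """
    dmp_set = set(dmp_probes)
    unknown = dmp_set - set(probe_table.index)
    if unknown:
        raise ValidationError(f"DMPs outside the background: {sorted(unknown)[:5]}")
    points = [(pid, row["chrom"], int(row["pos"])) for pid, row in probe_table.iterrows()]
    hits = overlap(points, loci)
    probes_in: dict[str, set] = {iv.name: set() for iv in loci}
    pooled_probes: set = set()
    for probe_id, iv in hits:
        probes_in[iv.name].add(probe_id)
        pooled_probes.add(probe_id)

    N, n = len(probe_table), len(dmp_set)
    records = []
    for name in sorted(probes_in):
        members = probes_in[name]
        K = len(members)
        k = len(members & dmp_set)
        if K == 0:
            records.append(EnrichmentRecord(name, N, 0, n, 0, 1.0, testable=False))
        elif alternative == "over":
            records.append(EnrichmentRecord(name, N, K, n, k, hypergeom_upper(N, K, n, k)))
        else:
            records.append(
                EnrichmentRecord(name, N, K, n, k, float(stats.hypergeom.cdf(k, N, K, n)))
            )
    records = _adjust(records)

    K_all = len(pooled_probes)
    k_all = len(pooled_probes & dmp_set)
    overall = EnrichmentRecord(
        "all_loci", N, K_all, n, k_all,
        hypergeom_upper(N, K_all, n, k_all) if K_all else 1.0,
        testable=K_all > 0,
    )
    return _records_frame(records), overall


# ----------------------------------------------------------- region classes
def region_class_enrichment(
    dmp_probes, class_labels: pd.Series, alternative: str = "over"
) -> pd.DataFrame:
    """DMP over-representation per region class vs the array background.

    ``class_labels`` maps every analyzable probe to its region class.
    """
    dmp_set = set(dmp_probes)
    unknown = dmp_set - set(class_labels.index)
    if unknown:
        raise ValidationError(f"DMPs outside the background: {sorted(unknown)[:5]}")
    selected = pd.Series(class_labels.index.isin(dmp_set), index=class_labels.index)
    return _records_frame(_category_records(class_labels, selected, alternative))


# -------------------------------------------------------------- gene sets
def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read tab-separated gene sets: name, description, members... (GMT)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def geneset_enrichment(
    genes,
    gene_sets: dict[str, set[str]],
    background,
    p_adj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric gene-set over-representation with BH across terms.

    Terms are intersected with the background before testing; an empty
    background is an error. The returned frame carries a ``significant``
    flag at ``p_adj <= p_adj_threshold``.
    """
    background = set(background)
    if not background:
        raise ValidationError("empty background gene universe")
    selected = set(genes) & background
    N, n = len(background), len(selected)
    records = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & background
        K = len(members)
        if K == 0:
            records.append(EnrichmentRecord(name, N, 0, n, 0, 1.0, testable=False))
            continue
        k = len(members & selected)
        records.append(EnrichmentRecord(name, N, K, n, k, hypergeom_upper(N, K, n, k)))
    frame = _records_frame(_adjust(records))
    frame["significant"] = frame["testable"] & (frame["p_adj"] <= p_adj_threshold)
    return frame


# ------------------------------------------------------------------- Fisher
def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of nonnegative integers.

    Two-sidedness by summation over all margin-fixed tables with probability
    <= that of the observed table. A zero margin yields p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("Fisher test needs a 2x2 table of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("Fisher test on a table with a zero margin; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
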