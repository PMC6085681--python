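"""Genomic-interval engine.

All coordinates are 0-based half-open (BED native); 1-based inclusive input
must be converted at the boundary. Probes are points and are treated as
length-1 intervals for overlap purposes.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

REGION_CLASSES = ("promoter", "exon", "intron", "intergenic")
CGI_RELATIONS = ("island", "shore", "shelf", "open_sea")

#: platform-convention distances from a CpG-island edge (bases)
SHORE_BP = 2000
SHELF_BP = 4000


@dataclass(frozen=True)
class GenomicInterval:
    """Named 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome must be nonempty")
        if not self.start < self.end:
            raise ValidationError(f"interval {self.name}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A named collection of genomic intervals with fast point/interval queries."""

    def __init__(self, intervals: list[GenomicInterval], name: str = "intervals"):
        self.name = name
        self.intervals = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def hits_at(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """Intervals sharing >= 1 base with [start, end), sorted by name then start."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        found = [h.data for h in tree.overlap(start, end)]
        return sorted(found, key=lambda iv: (iv.name, iv.start, iv.end))

    # ---------------------------------------------------------------- BED io
    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# 0-based half-open (BED)\n")
            for iv in sorted(self.intervals, key=lambda i: (i.chrom, i.start, i.end)):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "IntervalSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                iv_name = parts[3] if len(parts) > 3 else "."
                strand = parts[5] if len(parts) > 5 else "."
                intervals.append(GenomicInterval(chrom, start, end, iv_name, strand))
        return cls(intervals, name=name or Path(path).stem)


@dataclass(frozen=True)
class TranscriptModel:
    """Minimal transcript: gene name, strand, TSS and (optional) exons."""

    gene: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"transcript {self.gene}: unknown strand {self.strand!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValidationError(f"transcript {self.gene}: overlapping exons")

    def span(self) -> tuple[int, int]:
        """Gene-body span covering TSS and all exons."""
        starts = [self.tss] + [s for s, _ in self.exons]
        ends = [self.tss + 1] + [e for _, e in self.exons]
        return min(starts), max(ends)


@dataclass
class PromoterSet:
    """Strand-aware promoter windows, keyed by gene."""

    promoters: IntervalSet
    by_gene: dict[str, GenomicInterval] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.by_gene)


def build_promoters(
    models: list[TranscriptModel], upstream: int = 1000, downstream: int = 500
) -> PromoterSet:
    """Build per-gene promoter windows around each TSS.

    On the + strand a TSS at ``t`` yields ``[t - upstream, t + downstream)``;
    on the - strand the mirror window ``[t - downstream + 1, t + upstream + 1)``,
    so the window always covers ``upstream`` bases in the transcription-upstream
    direction and ``downstream`` bases downstream, TSS base included.
    Windows are truncated at position 0 with a warning.
    """
    intervals, by_gene = [], {}
    for model in models:
        if model.strand == "+":
            start, end = model.tss - upstream, model.tss + downstream
        else:
            start, end = model.tss - downstream + 1, model.tss + upstream + 1
        if start < 0:
            warnings.warn(f"promoter of {model.gene} truncated at chromosome start")
            start = 0
        iv = GenomicInterval(model.chrom, start, end, name=model.gene, strand=model.strand)
        intervals.append(iv)
        by_gene[model.gene] = iv
    return PromoterSet(promoters=IntervalSet(intervals, name="promoters"), by_gene=by_gene)


# -------------------------------------------------------------------- overlap
def overlap(query, subject: IntervalSet) -> list[tuple]:
    """All (query, subject-interval) pairs sharing at least one base.

    ``query`` is a list of either ``(name, chrom, pos)`` points (treated as
    length-1 intervals) or :class:`GenomicInterval`. Output order is query
    order, then subject name. A query chromosome absent from the subject
    yields no hits.
    """
    hits = []
    for q in query:
        if isinstance(q, GenomicInterval):
            found = subject.hits_at(q.chrom, q.start, q.end)
            key = q
        else:
            name, chrom, pos = q
            found = subject.hits_at(chrom, int(pos), int(pos) + 1)
            key = name
        hits.extend((key, iv) for iv in found)
    return hits


# ------------------------------------------------------------- region classes
def assign_region_class(
    chrom: str, pos: int, models: list[TranscriptModel], promoters: PromoterSet
) -> str:
    """Classify a probe position with precedence promoter > exon > intron > intergenic."""
    if promoters.promoters.hits_at(chrom, pos, pos + 1):
        return "promoter"
    in_body = False
    for model in models:
        if model.chrom != chrom:
            continue
        for s, e in model.exons:
            if s <= pos < e:
                return "exon"
        lo, hi = model.span()
        if lo <= pos < hi:
            in_body = True
    return "intron" if in_body else "intergenic"


# --------------------------------------------------------------- CGI relation
def cgi_edge_distance(chrom: str, pos: int, cgis: IntervalSet) -> float:
    """Distance in bases from a probe to the nearest CpG-island edge.

    0 inside an island; a probe 1 base past either edge has distance 1;
    inf if the chromosome carries no island.
    """
    best = np.inf
    for iv in cgis:
        if iv.chrom != chrom:
            continue
        if iv.start <= pos < iv.end:
            return 0
        d = iv.start - pos if pos < iv.start else pos - (iv.end - 1)
        best = min(best, d)
    return best


def cgi_relation(chrom: str, pos: int, cgis: IntervalSet) -> str:
    """island | shore (edge distance in (0, 2000]) | shelf ((2000, 4000]) | open_sea.

    The nearest island governs when several are in range.
    """
    d = cgi_edge_distance(chrom, pos, cgis)
    if d == 0:
        return "island"
    if d <= SHORE_BP:
        return "shore"
    if d <= SHELF_BP:
        return "shelf"
    return "open_sea"


def cgi_relation_table(probes: pd.DataFrame, cgis: IntervalSet) -> pd.Series:
    """Vectorised :func:`cgi_relation` for a probe table with chrom/pos columns."""
    out = pd.Series("open_sea", index=probes.index, dtype=object)
    for chrom, sub in probes.groupby("chrom", sort=False):
        ivs = sorted(
            (iv for iv in cgis if iv.chrom == chrom), key=lambda iv: iv.start
        )
        if not ivs:
            continue
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        pos = sub["pos"].to_numpy()
        # distance to each island's edges via sorted search; islands on one
        # chromosome are few, so a dense (n_probes x n_islands) min is fine
        left = starts[None, :] - pos[:, None]          # >0 when probe left of island
        right = pos[:, None] - (ends[None, :] - 1)     # >0 when probe right of island
        inside = (left <= 0) & (right <= 0)
        dist = np.where(inside, 0, np.maximum(left, right)).min(axis=1)
        rel = np.select(
            [dist == 0, dist <= SHORE_BP, dist <= SHELF_BP],
            ["island", "shore", "shelf"],
            default="open_sea",
        )
        out.loc[sub.index] = rel
    return out


# ------------------------------------------------------- DMP -> promoter table
def map_dmps_to_promoters(
    result, annotation_table: pd.DataFrame, promoters: PromoterSet, min_dmps: int = 1
) -> pd.DataFrame:
    """Aggregate called DMPs into per-gene differential-promoter records.

    Returns one row per gene with >= 1 DMP in its promoter window: DMP count,
    mean Δβ over those DMPs, a direction (``hyper``/``hypo``; ``mixed`` when
    the gene's DMPs disagree in sign) and a ``selected`` flag marking genes
    meeting the ``min_dmps`` threshold.
    """
    dmp_ids = [pid for pid in result.dmp_ids]
    if not dmp_ids:
        return pd.DataFrame(
            columns=["gene", "n_dmps", "mean_delta_beta", "direction", "selected"]
        ).set_index("gene")
    table = annotation_table.loc[dmp_ids]
    points = [(pid, row["chrom"], int(row["pos"])) for pid, row in table.iterrows()]
    hits = overlap(points, promoters.promoters)
    per_gene: dict[str, list[str]] = {}
    for probe_id, iv in hits:
        per_gene.setdefault(iv.name, []).append(probe_id)
    delta = result.table["delta_beta"]
    rows = []
    for gene in sorted(per_gene):
        probes = per_gene[gene]
        d = delta.loc[probes]
        if (d > 0).all():
            direction = "hyper"
        elif (d < 0).all():
            direction = "hypo"
        else:
            direction = "mixed"
        rows.append(
            {
                "gene": gene,
                "n_dmps": len(probes),
                "mean_delta_beta": float(d.mean()),
                "direction": direction,
                "selected": len(probes) >= min_dmps,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# ----------------------------------------------------------- transcript table io
def transcripts_to_tsv(models: list[TranscriptModel], path: str | Path) -> None:
    rows = [
        {
            "gene": m.gene,
            "chrom": m.chrom,
            "strand": m.strand,
            "tss": m.tss,
            "exons": ";".join(f"{s}-{e}" for s, e in m.exons),
        }
        for m in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def transcripts_from_tsv(path: str | Path) -> list[TranscriptModel]:
    raw = pd.read_csv(path, sep="\t", keep_default_na=False)
    models = []
    for _, row in raw.iterrows():
        exons = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in str(row["exons"]).split(";")
            if part and part != "nan"
        )
        models.append(
            TranscriptModel(
                gene=row["gene"], chrom=row["chrom"], strand=row["strand"],
                tss=int(row["tss"]), exons=exons,
            )
        )
    return models
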