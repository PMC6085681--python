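"""Interval engine: promoters, overlap, region classes, CGI relations."""
import numpy as np
import pandas as pd
import pytest

from methpair import (
    GenomicInterval,
    IntervalSet,
    TranscriptModel,
    ValidationError,
    assign_region_class,
    build_promoters,
    cgi_relation,
    map_dmps_to_promoters,
    overlap,
)
from methpair.annotation import cgi_edge_distance, cgi_relation_table
from methpair.differential import DifferentialResult


def brute_force_overlap(points, intervals):
    """O(n*m) all-pairs scan; the independent oracle for the interval engine."""
    hits = set()
    for name, chrom, pos in points:
        for iv in intervals:
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                hits.add((name, iv.name))
    return hits


class TestPromoters:
    def test_plus_strand_window(self):
        ps = build_promoters([TranscriptModel("g", "chr1", "+", 10000)])
        iv = ps.by_gene["g"]
        assert (iv.start, iv.end) == (9000, 10500)

    def test_minus_strand_window_mirrors_upstream(self):
        ps = build_promoters([TranscriptModel("g", "chr1", "-", 10000)])
        iv = ps.by_gene["g"]
        assert iv.length == 1500
        # transcription-upstream side extends to higher coordinates
        assert iv.end - 10000 > 10000 - iv.start

    def test_every_promoter_has_length_1500(self):
        models = [TranscriptModel(f"g{i}", "chr1", s, 50000 + 7000 * i)
                  for i, s in enumerate("+-+-")]
        ps = build_promoters(models)
        assert all(iv.length == 1500 for iv in ps.by_gene.values())

    def test_half_open_boundary_excludes_upstream_edge(self):
        ps = build_promoters([TranscriptModel("g", "chr1", "+", 10000)])
        assert not overlap([("p", "chr1", 8999)], ps.promoters)
        assert overlap([("p", "chr1", 9000)], ps.promoters)

    def test_truncation_at_chromosome_start_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            ps = build_promoters([TranscriptModel("g", "chr1", "+", 500)])
        assert ps.by_gene["g"].start == 0

    def test_unknown_strand_names_the_transcript(self):
        with pytest.raises(ValidationError, match="gX"):
            TranscriptModel("gX", "chr1", "?", 1000)


class TestOverlap:
    def test_point_on_start_hits_point_on_end_misses(self):
        s = IntervalSet([GenomicInterval("chr1", 100, 200, "a")])
        assert len(overlap([("p", "chr1", 100)], s)) == 1
        assert len(overlap([("p", "chr1", 200)], s)) == 0

    def test_absent_chromosome_yields_no_hits(self):
        s = IntervalSet([GenomicInterval("chr1", 100, 200, "a")])
        assert overlap([("p", "chr9", 150)], s) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        chroms = ["chr1", "chr2", "chr3"]
        points = [(f"p{i}", chroms[rng.integers(3)], int(rng.integers(0, 50_000)))
                  for i in range(1000)]
        intervals = []
        for i in range(200):
            start = int(rng.integers(0, 49_000))
            intervals.append(GenomicInterval(chroms[rng.integers(3)], start,
                                             start + int(rng.integers(1, 2000)),
                                             name=f"iv{i}"))
        s = IntervalSet(intervals)
        found = {(name, iv.name) for name, iv in overlap(points, s)}
        assert found == brute_force_overlap(points, intervals)

    def test_symmetric_under_role_swap(self):
        rng = np.random.default_rng(9)
        a = [GenomicInterval("chr1", int(s), int(s) + 500, f"a{i}")
             for i, s in enumerate(rng.integers(0, 20_000, 30))]
        b = [GenomicInterval("chr1", int(s), int(s) + 700, f"b{i}")
             for i, s in enumerate(rng.integers(0, 20_000, 30))]
        ab = {(q.name, iv.name) for q, iv in overlap(a, IntervalSet(b))}
        ba = {(iv.name, q.name) for q, iv in overlap(b, IntervalSet(a))}
        assert ab == ba

    def test_output_order_is_query_then_subject_name(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 1000, "z"),
                         GenomicInterval("chr1", 0, 1000, "a")])
        hits = overlap([("p1", "chr1", 5), ("p0", "chr1", 5)], s)
        assert [(q, iv.name) for q, iv in hits] == [
            ("p1", "a"), ("p1", "z"), ("p0", "a"), ("p0", "z")]


class TestRegionClass:
    def setup_method(self):
        self.models = [
            TranscriptModel("gA", "chr1", "+", 10000, exons=((10000, 10200), (11000, 11400))),
            TranscriptModel("gB", "chr1", "+", 30000, exons=((30000, 30100), (32000, 32500))),
        ]
        self.promoters = build_promoters(self.models)

    def test_promoter_beats_other_genes_intron(self):
        # gB's promoter [29000, 30500) overlapping a hypothetical intron zone
        models = self.models + [
            TranscriptModel("gC", "chr1", "+", 28000, exons=((28000, 28050), (31000, 31200)))
        ]
        promoters = build_promoters(models)
        assert assign_region_class("chr1", 29500, models, promoters) == "promoter"

    def test_unannotated_position_is_intergenic(self):
        assert assign_region_class("chr1", 500_000, self.models, self.promoters) == "intergenic"

    def test_hand_built_fixture(self):
        expected = {
            9000: "promoter",     # gA promoter start
            10499: "promoter",
            10500: "exon",        # inside gA exon 1 but past promoter window? -> no: exon1 ends 10200
            10600: "intron",      # between gA exons
            11100: "exon",        # gA exon 2
            11500: "intergenic",  # past gA body, before gB promoter
            29000: "promoter",    # gB promoter
            30700: "intron",
            32100: "exon",
            40000: "intergenic",
        }
        # position 10500 sits in neither exon: correct expectation is intron
        expected[10500] = "intron"
        for pos, cls in expected.items():
            assert assign_region_class("chr1", pos, self.models, self.promoters) == cls, pos


class TestCgiRelation:
    def setup_method(self):
        self.cgis = IntervalSet([GenomicInterval("chr1", 1000, 2000, "cgi1")])

    def test_inside_island(self):
        assert cgi_relation("chr1", 1500, self.cgis) == "island"

    @pytest.mark.parametrize("pos,expected", [
        (2000, "shore"), (3999, "shore"), (4000, "shelf"),
        (5999, "shelf"), (6000, "open_sea"),
        (999, "shore"), (0, "shore"),
    ])
    def test_edge_distances_right_and_left(self, pos, expected):
        assert cgi_relation("chr1", pos, self.cgis) == expected

    def test_nearest_island_governs_between_two(self):
        cgis = IntervalSet([GenomicInterval("chr1", 0, 100, "a"),
                            GenomicInterval("chr1", 10000, 10100, "b")])
        # 1500 bases from a's edge, 8400 from b's: shore via a
        assert cgi_relation("chr1", 99 + 1500, cgis) == "shore"

    def test_chromosome_without_island_is_open_sea(self):
        assert cgi_relation("chr2", 1500, self.cgis) == "open_sea"

    def test_vectorised_table_matches_scalar_and_brute_force(self):
        rng = np.random.default_rng(13)
        cgis = IntervalSet([
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(200, 800)), f"c{i}")
            for i, s in enumerate(sorted(rng.integers(0, 80_000, 12)))
        ])
        probes = pd.DataFrame({
            "chrom": "chr1",
            "pos": rng.integers(0, 90_000, 300),
        }, index=[f"p{i}" for i in range(300)])
        table = cgi_relation_table(probes, cgis)
        for pid, row in probes.iterrows():
            # brute-force nearest-edge scan
            dists = []
            for iv in cgis:
                if iv.start <= row["pos"] < iv.end:
                    dists.append(0)
                elif row["pos"] < iv.start:
                    dists.append(iv.start - row["pos"])
                else:
                    dists.append(row["pos"] - (iv.end - 1))
            d = min(dists)
            expected = ("island" if d == 0 else "shore" if d <= 2000
                        else "shelf" if d <= 4000 else "open_sea")
            assert table.loc[pid] == expected == cgi_relation("chr1", int(row["pos"]), cgis)
            assert cgi_edge_distance("chr1", int(row["pos"]), cgis) == d


def _result_from_deltas(deltas: dict[str, float], called=None) -> DifferentialResult:
    called = set(deltas) if called is None else called
    table = pd.DataFrame({
        "delta_beta": pd.Series(deltas),
        "statistic": 1.0, "p_raw": 0.01, "p_adj": 0.01,
        "n_pairs": 10, "degenerate": False,
        "is_dmp": [pid in called for pid in deltas],
        "direction": ["hyper" if d > 0 else "hypo" for d in deltas.values()],
    })
    table.index.name = "probe_id"
    return DifferentialResult(table=table, delta_threshold=0.15, q_threshold=0.05, scale="m")


class TestPromoterMapping:
    def _setup(self, probe_pos: dict[str, int]):
        ann = pd.DataFrame({"chrom": "chr1", "pos": pd.Series(probe_pos)})
        models = [TranscriptModel("g1", "chr1", "+", 10000),
                  TranscriptModel("g2", "chr1", "+", 50000)]
        return ann, build_promoters(models)

    def test_consistent_signs_give_direction_and_count(self):
        ann, proms = self._setup({"a": 9500, "b": 9600})
        res = _result_from_deltas({"a": 0.2, "b": 0.3})
        out = map_dmps_to_promoters(res, ann, proms)
        assert out.loc["g1", "n_dmps"] == 2
        assert out.loc["g1", "direction"] == "hyper"
        assert out.loc["g1", "mean_delta_beta"] == pytest.approx(0.25)

    def test_conflicting_signs_are_mixed(self):
        ann, proms = self._setup({"a": 9500, "b": 9600})
        out = map_dmps_to_promoters(_result_from_deltas({"a": 0.2, "b": -0.2}), ann, proms)
        assert out.loc["g1", "direction"] == "mixed"

    def test_min_dmps_flag(self):
        pos = {}
        deltas = {}
        # gene g1 gets 2 DMPs, g2 gets 3
        for i in range(2):
            pos[f"a{i}"] = 9500 + i * 10
            deltas[f"a{i}"] = 0.2
        for i in range(3):
            pos[f"b{i}"] = 49500 + i * 10
            deltas[f"b{i}"] = 0.2
        ann, proms = self._setup(pos)
        out = map_dmps_to_promoters(_result_from_deltas(deltas), ann, proms, min_dmps=3)
        assert not out.loc["g1", "selected"] and out.loc["g2", "selected"]
        assert int(out["selected"].sum()) == 1
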