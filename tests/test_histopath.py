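"""Feature stratification, uniqueness rule, cross-feature overlap and the
rete-peg correlation screen."""
import numpy as np
import pandas as pd
import pytest

from methpair import (
    HistoFeatureTable,
    ValidationError,
    correlate_rete_peg,
    cross_feature_overlap,
    simulate_histopathology,
    stratified_analysis,
    stratify,
    top_unique_for_pca,
    unique_dmps,
)
from methpair.differential import DifferentialResult
from methpair.histopath import StratifiedResult
from methpair.simulate import SimulationConfig

from conftest import paired_matrix_from_betas


def _result(dmps, universe, p_adj=None, deltas=None) -> DifferentialResult:
    universe = list(universe)
    table = pd.DataFrame({
        "delta_beta": [deltas.get(p, 0.2) if deltas else 0.2 for p in universe],
        "statistic": 1.0,
        "p_raw": 0.01,
        "p_adj": [p_adj.get(p, 0.5) if p_adj else (0.01 if p in dmps else 0.5)
                  for p in universe],
        "n_pairs": 10,
        "degenerate": False,
        "is_dmp": [p in dmps for p in universe],
        "direction": "hyper",
    }, index=pd.Index(universe, name="probe_id"))
    return DifferentialResult(table=table, delta_threshold=0.15, q_threshold=0.05, scale="m")


def _histo(assignments: dict, lengths=None) -> HistoFeatureTable:
    feats = pd.DataFrame(assignments)
    feats.index = [f"P{i + 1:02d}" for i in range(len(feats))]
    feats.index.name = "patient"
    return HistoFeatureTable(
        features=feats,
        rete_peg_length_um=None if lengths is None
        else pd.Series(lengths, index=feats.index),
    )


class TestStratify:
    def test_default_cohort_strata_sizes(self, study):
        present, absent = stratify(study.matrix, study.histopathology, "munro_microabscess")
        assert len(present.patients) == 11
        assert len(absent.patients) == 10
        present.validate_paired()
        absent.validate_paired()

    def test_no_missing_values_partition_cohort(self, study):
        present, absent = stratify(study.matrix, study.histopathology,
                                   "focal_hypergranulosis")
        assert len(present.patients) + len(absent.patients) == 24

    def test_one_sided_feature_is_refused(self):
        rng = np.random.default_rng(0)
        matrix = paired_matrix_from_betas(rng.uniform(0.3, 0.7, (5, 6)),
                                          rng.uniform(0.3, 0.7, (5, 6)))
        histo = _histo({"f": ["present"] * 6})
        with pytest.raises(ValidationError, match="strata"):
            stratify(matrix, histo, "f")

    def test_unknown_feature_is_refused(self, study):
        with pytest.raises(ValidationError, match="unknown"):
            stratify(study.matrix, study.histopathology, "nope")


class TestUniqueDmps:
    def test_set_logic(self):
        universe = [f"p{i}" for i in range(6)]
        a = _result({"p1", "p2", "p3"}, universe)
        b = _result({"p2", "p3", "p4"}, universe)
        ua, ub, common = unique_dmps(a, b)
        assert (ua, ub, common) == ({"p1"}, {"p4"}, {"p2", "p3"})

    def test_identical_results_have_no_unique(self):
        universe = [f"p{i}" for i in range(4)]
        a = _result({"p0", "p1"}, universe)
        ua, ub, common = unique_dmps(a, a)
        assert ua == ub == set() and common == {"p0", "p1"}

    def test_role_swap_symmetry(self):
        universe = [f"p{i}" for i in range(6)]
        a = _result({"p0", "p1"}, universe)
        b = _result({"p1", "p5"}, universe)
        ua, ub, common = unique_dmps(a, b)
        ub2, ua2, common2 = unique_dmps(b, a)
        assert (ua, ub, common) == (ua2, ub2, common2)

    def test_universe_mismatch_is_hard_error(self):
        a = _result({"p0"}, ["p0", "p1"])
        b = _result({"p0"}, ["p0", "p2"])
        with pytest.raises(ValidationError):
            unique_dmps(a, b)

    def test_strict_counterpart_rule_drops_borderline(self):
        universe = ["p0", "p1"]
        a = _result({"p0", "p1"}, universe)
        # counterpart: p0 significant on p_adj but fails the joint rule
        b = _result(set(), universe, p_adj={"p0": 0.01, "p1": 0.9})
        ua_joint, _, _ = unique_dmps(a, b, counterpart_rule="joint")
        ua_strict, _, _ = unique_dmps(a, b, counterpart_rule="padj")
        assert ua_joint == {"p0", "p1"}
        assert ua_strict == {"p1"}

    def test_feature_spikes_recovered_into_unique_present(self, filtered_matrix, study):
        res = stratified_analysis(filtered_matrix, study.histopathology,
                                  "munro_microabscess")
        spiked = set(study.truth.feature_unique["munro_microabscess"])
        spiked &= set(filtered_matrix.probe_ids)
        recovered = len(res.unique_present & spiked) / len(spiked)
        assert recovered >= 0.9
        contamination = len(res.unique_present - spiked) / max(len(res.unique_present), 1)
        assert contamination <= 0.10


class TestCrossFeature:
    def _stratified(self, feature, unique_present, universe):
        present = _result(set(unique_present), universe)
        absent = _result(set(), universe)
        return StratifiedResult(
            feature=feature, present_result=present, absent_result=absent,
            unique_present=set(unique_present), unique_absent=set(), common=set(),
        )

    def test_disjoint_unique_sets_have_empty_intersections(self):
        universe = [f"p{i}" for i in range(9)]
        results = [self._stratified(f, universe[i * 3:(i + 1) * 3], universe)
                   for i, f in enumerate("abc")]
        table = cross_feature_overlap(results)
        assert (table["n"] == 0).all()

    def test_constructed_shared_spike_recovered_exactly(self):
        universe = [f"p{i}" for i in range(10)]
        shared = {"p0", "p1"}
        results = [
            self._stratified("a", shared | {"p3"}, universe),
            self._stratified("b", shared | {"p4"}, universe),
            self._stratified("c", shared | {"p5"}, universe),
        ]
        table = cross_feature_overlap(results)
        assert table.loc["a & b & c", "n"] == 2
        assert set(table.loc["a & b & c", "probes"].split(",")) == shared

    def test_cardinalities_match_brute_force(self):
        rng = np.random.default_rng(2)
        universe = [f"p{i}" for i in range(40)]
        sets = [set(rng.choice(universe, 12, replace=False)) for _ in range(3)]
        results = [self._stratified(f, s, universe) for f, s in zip("abc", sets)]
        table = cross_feature_overlap(results)
        assert table.loc["a & b", "n"] == len(sets[0] & sets[1])
        assert table.loc["a & c", "n"] == len(sets[0] & sets[2])
        assert table.loc["b & c", "n"] == len(sets[1] & sets[2])
        assert table.loc["a & b & c", "n"] == len(sets[0] & sets[1] & sets[2])

    def test_single_result_refused(self):
        with pytest.raises(ValidationError):
            cross_feature_overlap([self._stratified("a", {"p0"}, ["p0"])])


class TestReteCorrelation:
    def test_perfect_linear_relation_has_unit_r(self):
        lengths = np.linspace(100, 600, 8)
        disease = (0.2 + 0.001 * lengths)[None, :]
        matrix = paired_matrix_from_betas(disease, np.full((1, 8), 0.4))
        histo = _histo({"f": ["present"] * 8}, lengths=lengths)
        records = correlate_rete_peg(matrix, histo)
        assert records["r"].iloc[0] == pytest.approx(1.0)
        assert records["tier"].iloc[0] == "high"

    def test_constant_beta_probe_excluded(self):
        lengths = np.linspace(100, 600, 8)
        matrix = paired_matrix_from_betas(np.full((1, 8), 0.5), np.full((1, 8), 0.4))
        records = correlate_rete_peg(matrix, _histo({"f": ["present"] * 8}, lengths))
        assert bool(records["excluded"].iloc[0])
        assert records["tier"].iloc[0] == "none"

    def test_too_few_lengths_refused(self):
        matrix = paired_matrix_from_betas(np.full((1, 4), 0.5), np.full((1, 4), 0.4))
        histo = _histo({"f": ["present"] * 4},
                       lengths=[200.0, np.nan, np.nan, np.nan])
        with pytest.raises(ValidationError, match=">= 4"):
            correlate_rete_peg(matrix, histo)

    def test_simulated_length_probes_reach_high_tier(self, filtered_matrix, study):
        length_ids = [p for p in study.truth.length_probe_signs
                      if p in set(filtered_matrix.probe_ids)]
        records = correlate_rete_peg(filtered_matrix, study.histopathology,
                                     probe_ids=length_ids)
        assert (records["tier"] == "high").mean() >= 0.8
        for pid, sign in study.truth.length_probe_signs.items():
            assert np.sign(records.loc[pid, "r"]) == sign

    def test_tier_thresholds_respected(self, filtered_matrix, study):
        records = correlate_rete_peg(filtered_matrix, study.histopathology)
        tiers = records[records["tier"] != "none"]
        assert (tiers["p_raw"] <= 0.05).all()
        assert (tiers["r"].abs() >= 0.4).all()
        assert (records.loc[records["tier"] == "high", "r"].abs() >= 0.6).all()


class TestTopUnique:
    def test_orders_by_adjusted_p(self):
        universe = ["a", "b", "c"]
        res = _result(set(universe), universe,
                      p_adj={"a": 0.03, "b": 0.01, "c": 0.02})
        assert top_unique_for_pca(set(universe), res, k=3) == ["b", "c", "a"]

    def test_p_ties_broken_by_effect_size(self):
        universe = ["a", "b"]
        res = _result(set(universe), universe, p_adj={"a": 0.01, "b": 0.01},
                      deltas={"a": 0.2, "b": -0.4})
        assert top_unique_for_pca(set(universe), res, k=1) == ["b"]

    def test_k_larger_than_set_returns_everything(self):
        universe = ["a", "b"]
        res = _result(set(universe), universe)
        assert len(top_unique_for_pca(set(universe), res, k=100)) == 2

    def test_empty_set_refused(self):
        res = _result({"a"}, ["a"])
        with pytest.raises(ValidationError):
            top_unique_for_pca(set(), res)
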