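"""Synthetic paired methylation-array data with known ground truth.

The generator emulates the structure of a paired lesional / adjacent-normal
skin methylation study: ~24 patient pairs on a bead-array-like probe set
with a bimodal baseline β distribution, M-scale Gaussian noise, per-patient
random effects, additive batch offsets, a hyper-skewed spiked DMP set,
histopathology-feature-linked effects confined to feature-positive
patients, and probes whose lesional β tracks a continuous rete-peg length.

Every random draw is derived from ``SimulationConfig.seed``; identical
configs produce byte-identical outputs.
"""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, IntervalSet, TranscriptModel, cgi_relation_table, transcripts_to_tsv
from .containers import ABSENT, DISEASE, NORMAL, PRESENT, BetaMatrix, HistoFeatureTable, ProbeAnnotation
from .exceptions import ConfigurationError
from .preprocess import beta_to_m, m_to_beta

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 7))

#: spiked means must stay inside this open interval on the β scale
SAFE_LOW, SAFE_HIGH = 0.02, 0.98
#: spiked baselines are drawn from a narrower band so the check above holds
#: with margin even after the effect shift
DRAW_LOW, DRAW_HIGH = 0.05, 0.93


@dataclass(frozen=True)
class FeatureSpec:
    """One binary histopathology feature and its methylation footprint.

    ``positive_fraction`` / ``na_fraction`` are fractions of all patients
    (rounded to exact counts); ``n_unique_dmps`` probes receive a
    ``effect_size`` hypermethylation shift in the lesional tissue of
    feature-positive patients only.
    """

    name: str
    positive_fraction: float
    n_unique_dmps: int = 0
    effect_size: float = 0.25
    na_fraction: float | None = None  # None -> SimulationConfig.na_fraction

    def counts(self, n_patients: int, default_na: float) -> tuple[int, int, int]:
        """(present, absent, missing) patient counts."""
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ConfigurationError(f"feature {self.name}: positive_fraction outside [0, 1]")
        na_frac = default_na if self.na_fraction is None else self.na_fraction
        if not 0.0 <= na_frac <= 1.0:
            raise ConfigurationError(f"feature {self.name}: na_fraction outside [0, 1]")
        n_na = round(na_frac * n_patients)
        n_pos = round(self.positive_fraction * n_patients)
        n_abs = n_patients - n_na - n_pos
        if n_abs < 0:
            raise ConfigurationError(f"feature {self.name}: fractions exceed the cohort")
        return n_pos, n_abs, n_na


def cohort_features(
    n_unique_dmps: int = 0, effect_size: float = 0.25
) -> tuple[FeatureSpec, ...]:
    """Default histopathology preset for a 24-patient cohort.

    Munro's microabscess 11 present / 10 absent / 3 not assessable, focal
    hypergranulosis 7 / 17, Kogoj's microabscess 9 / 15. Feature-linked
    methylation effects, when requested, are attached to the Munro feature.
    """
    return (
        FeatureSpec("munro_microabscess", 11 / 24, n_unique_dmps, effect_size, na_fraction=3 / 24),
        FeatureSpec("focal_hypergranulosis", 7 / 24, 0, effect_size, na_fraction=0.0),
        FeatureSpec("kogoj_microabscess", 9 / 24, 0, effect_size, na_fraction=0.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic study.

    The defaults are the study conditions the pipeline is exercised under:
    24 patient pairs, 20,000 probes, M-scale noise SD 0.5, a 62.5%-hyper
    spiked DMP set at |Δβ| = 0.25, two batches, and the default 24-patient
    histopathology preset.
    """

    n_patients: int = 24
    n_probes: int = 20_000
    seed: int = 0
    baseline_beta_dist: str | tuple[float, float] = "bimodal"
    noise_sd_m: float = 0.5
    patient_sd_m: float | None = None  # None -> noise_sd_m / 2
    n_dmp_hyper: int = 500
    n_dmp_hypo: int = 300
    delta_beta_effect: float = 0.25
    feature_specs: tuple[FeatureSpec, ...] = field(default_factory=cohort_features)
    n_length_probes: int = 0
    length_range_um: tuple[float, float] = (150.0, 600.0)
    length_slope: float = 0.001  # β per µm; gives population |r| ~ 0.8 at default noise
    n_batches: int = 2
    batch_offsets_m: tuple[float, ...] = (0.0, 0.3)
    na_fraction: float = 0.0
    psors_fraction: float = 0.25
    n_psors_loci: int = 10
    region_mix: tuple[tuple[str, float], ...] = (
        ("promoter", 0.25), ("exon", 0.10), ("intron", 0.40), ("intergenic", 0.25),
    )
    frac_type1: float = 0.2
    frac_sex: float = 0.02
    frac_non_cpg: float = 0.01
    frac_polymorphic: float = 0.01
    frac_control: float = 0.005
    frac_repeat: float = 0.11
    n_detection_fail: int = 10
    n_bead_fail: int = 10

    @property
    def patient_sd(self) -> float:
        return self.noise_sd_m / 2 if self.patient_sd_m is None else self.patient_sd_m

    def n_spiked(self) -> int:
        return (
            self.n_dmp_hyper
            + self.n_dmp_hypo
            + sum(f.n_unique_dmps for f in self.feature_specs)
            + self.n_length_probes
        )

    def validate(self) -> None:
        if self.n_probes < 100:
            raise ConfigurationError("need at least 100 probes")
        if self.n_patients < 3:
            raise ConfigurationError("need at least 3 patient pairs")
        if not 0.0 < self.delta_beta_effect < 1.0:
            raise ConfigurationError("delta_beta_effect must lie in (0, 1)")
        if self.n_spiked() > self.n_probes:
            raise ConfigurationError("more spiked probes than probes")
        if len(self.batch_offsets_m) != self.n_batches:
            raise ConfigurationError("batch_offsets_m length must equal n_batches")
        if not 0.0 <= self.psors_fraction <= 1.0:
            raise ConfigurationError("psors_fraction outside [0, 1]")
        for delta in [self.delta_beta_effect] + [
            f.effect_size for f in self.feature_specs if f.n_unique_dmps
        ]:
            if DRAW_LOW >= DRAW_HIGH - delta:
                raise ConfigurationError(
                    f"effect {delta} leaves no feasible baseline band for spiked probes"
                )
        for f in self.feature_specs:
            f.counts(self.n_patients, self.na_fraction)


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def _patient_ids(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


# =========================================================== annotation layer
@dataclass
class SimulatedAnnotation:
    """Probe annotation plus the interval sets and transcripts it refers to."""

    probes: ProbeAnnotation
    psors_loci: IntervalSet
    cgi_intervals: IntervalSet
    transcripts: list[TranscriptModel]


def _apportion(total: int, weights: list[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` by ``weights``."""
    raw = [total * w / sum(weights) for w in weights]
    counts = [math.floor(x) for x in raw]
    rest = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rest]:
        counts[i] += 1
    return counts


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Lay probes along a small synthetic genome and annotate them.

    Promoter-class probes come in 1–4-probe clusters, each backed by a
    synthetic transcript whose promoter window contains the cluster; CpG
    islands are interspersed so that island/shore/shelf/open-sea relations
    all occur; susceptibility-like loci cover ``psors_fraction`` of the
    probes exactly (deterministic placement under the seed).
    """
    config.validate()
    rng = _rng(config, 1)

    n_sex = round(config.frac_sex * config.n_probes)
    n_auto = config.n_probes - n_sex

    class_names = [name for name, _ in config.region_mix]
    class_counts = dict(zip(class_names, _apportion(n_auto, [w for _, w in config.region_mix])))

    # promoter probes arrive in gene clusters of 1-4
    cluster_sizes = []
    remaining = class_counts.get("promoter", 0)
    while remaining > 0:
        k = min(int(rng.choice([1, 2, 3, 4], p=[0.4, 0.3, 0.2, 0.1])), remaining)
        cluster_sizes.append(k)
        remaining -= k
    units: list[tuple[str, int]] = [("promoter", k) for k in cluster_sizes]
    for cls in class_names:
        if cls == "promoter":
            continue
        units.extend([(cls, 1)] * class_counts[cls])
    rng.shuffle(units)

    # distribute units over autosomes in contiguous chunks of similar probe
    # count; a promoter cluster split at a chromosome boundary carries its
    # remainder over as a separate gene so no probe is lost
    per_chrom = _apportion(n_auto, [1.0] * len(AUTOSOMES))
    chrom_units: dict[str, list[tuple[str, int]]] = {c: [] for c in AUTOSOMES}
    queue = deque(units)
    for chrom, quota in zip(AUTOSOMES, per_chrom):
        placed = 0
        while placed < quota:
            cls, k = queue.popleft()
            take = min(k, quota - placed)
            chrom_units[chrom].append((cls, take))
            if take < k:
                queue.appendleft((cls, k - take))
            placed += take

    rows, transcripts = [], []
    gene_no = 0
    for chrom in AUTOSOMES:
        pos = 10_000
        for cls, k in chrom_units[chrom]:
            positions = [pos]
            for _ in range(k - 1):
                positions.append(positions[-1] + int(rng.integers(120, 250)))
            if cls == "promoter":
                gene_no += 1
                gene = f"G{gene_no:05d}"
                strand = "+" if rng.random() < 0.5 else "-"
                tss = positions[0] + 400
                exon = (tss, tss + 200) if strand == "+" else (tss - 200, tss)
                transcripts.append(
                    TranscriptModel(gene=gene, chrom=chrom, strand=strand, tss=tss, exons=(exon,))
                )
            else:
                gene = ""
            for p in positions:
                rows.append({"chrom": chrom, "pos": p, "region_class": cls, "gene": gene})
            pos = positions[-1] + int(rng.integers(1500, 3000))

    # sex-chromosome probes
    for i in range(n_sex):
        chrom = "chrX" if i % 2 == 0 else "chrY"
        base = 10_000 + (i // 2) * 2000
        rows.append({"chrom": chrom, "pos": base, "region_class": "intergenic", "gene": ""})

    table = pd.DataFrame(rows)
    chrom_order = {c: i for i, c in enumerate(AUTOSOMES + ("chrX", "chrY"))}
    table = table.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    table.index = pd.Index([f"cg{i:08d}" for i in range(len(table))], name="probe_id")

    # disjoint special-probe flags among autosomal probes
    auto_idx = np.flatnonzero(table["chrom"].isin(AUTOSOMES).to_numpy())
    perm = _rng(config, 2).permutation(auto_idx)
    n_control = round(config.frac_control * config.n_probes)
    n_non_cpg = round(config.frac_non_cpg * config.n_probes)
    n_poly = round(config.frac_polymorphic * config.n_probes)
    flags = {"is_control": n_control, "is_cpg": n_non_cpg, "is_polymorphic": n_poly}
    table["is_control"] = False
    table["is_cpg"] = True
    table["is_polymorphic"] = False
    cursor = 0
    for col, count in flags.items():
        chosen = perm[cursor : cursor + count]
        cursor += count
        if col == "is_cpg":
            table.iloc[chosen, table.columns.get_loc(col)] = False
        else:
            table.iloc[chosen, table.columns.get_loc(col)] = True

    rng3 = _rng(config, 3)
    table["probe_type"] = np.where(rng3.random(len(table)) < config.frac_type1, "I", "II")
    table["in_repeat"] = rng3.random(len(table)) < config.frac_repeat

    # CpG islands: every ~30th probe anchors a 500 bp island
    cgi_intervals = []
    rng4 = _rng(config, 4)
    for chrom in AUTOSOMES:
        sub = table[table["chrom"] == chrom]
        offset = int(rng4.integers(0, 30))
        for j, (pid, row) in enumerate(sub.iterrows()):
            if (j + offset) % 30 == 0:
                cgi_intervals.append(
                    GenomicInterval(chrom, max(0, row["pos"] - 200), row["pos"] + 300,
                                    name=f"CGI_{len(cgi_intervals) + 1:04d}")
                )
    cgis = IntervalSet(cgi_intervals, name="cgi")
    table["cgi_relation"] = cgi_relation_table(table, cgis)

    psors = _place_psors_loci(config, table)

    cols = ["chrom", "pos", "probe_type", "is_cpg", "is_control", "is_polymorphic",
            "region_class", "cgi_relation", "in_repeat", "gene"]
    return SimulatedAnnotation(
        probes=ProbeAnnotation(table[cols]),
        psors_loci=psors,
        cgi_intervals=cgis,
        transcripts=transcripts,
    )


def _place_psors_loci(config: SimulationConfig, table: pd.DataFrame) -> IntervalSet:
    """Non-overlapping loci covering exactly round(psors_fraction * n_probes) probes."""
    covered = round(config.psors_fraction * config.n_probes)
    if covered == 0 or config.n_psors_loci == 0:
        return IntervalSet([], name="psors")
    auto = table[table["chrom"].isin(AUTOSOMES)]
    if covered > len(auto):
        raise ConfigurationError("psors_fraction exceeds the autosomal probe count")
    n_loci = min(config.n_psors_loci, covered)
    counts = _apportion(covered, [1.0] * n_loci)
    chroms = auto["chrom"].to_numpy()
    positions = auto["pos"].to_numpy()
    bounds = np.linspace(0, len(auto), n_loci + 1).astype(int)
    rng = _rng(config, 5)
    intervals = []
    for i, cnt in enumerate(counts):
        a, b = bounds[i], bounds[i + 1]
        candidates = [
            s for s in range(a, max(a, b - cnt) + 1)
            if s + cnt <= len(auto) and chroms[s] == chroms[s + cnt - 1]
        ]
        if not candidates:
            raise ConfigurationError(
                f"cannot place susceptibility locus {i + 1}: no contiguous run of {cnt} probes"
            )
        s = int(rng.choice(candidates))
        intervals.append(
            GenomicInterval(chroms[s], int(positions[s]), int(positions[s + cnt - 1]) + 1,
                            name=f"PSORS{i + 1}")
        )
    return IntervalSet(intervals, name="psors")


# ========================================================== ground truth layer
@dataclass
class GroundTruth:
    """What was spiked where; every probe appears in at most one category."""

    hyper_ids: list[str] = field(default_factory=list)
    hypo_ids: list[str] = field(default_factory=list)
    feature_unique: dict[str, list[str]] = field(default_factory=dict)
    length_probe_signs: dict[str, int] = field(default_factory=dict)
    batch_offsets: dict[str, float] = field(default_factory=dict)
    detection_fail_ids: list[str] = field(default_factory=list)
    bead_fail_ids: list[str] = field(default_factory=list)

    @property
    def true_dmp_ids(self) -> set[str]:
        return set(self.hyper_ids) | set(self.hypo_ids)

    def categories(self) -> list[set[str]]:
        cats = [set(self.hyper_ids), set(self.hypo_ids), set(self.length_probe_signs),
                set(self.detection_fail_ids), set(self.bead_fail_ids)]
        cats.extend(set(v) for v in self.feature_unique.values())
        return cats

    def assert_disjoint(self) -> None:
        cats = self.categories()
        total = sum(len(c) for c in cats)
        union = set().union(*cats) if cats else set()
        if total != len(union):
            raise ConfigurationError("ground-truth categories overlap")

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for pid in self.hyper_ids:
            rows.append({"probe_id": pid, "category": "dmp_hyper", "detail": ""})
        for pid in self.hypo_ids:
            rows.append({"probe_id": pid, "category": "dmp_hypo", "detail": ""})
        for feat, ids in self.feature_unique.items():
            for pid in ids:
                rows.append({"probe_id": pid, "category": "feature_unique", "detail": feat})
        for pid, sign in self.length_probe_signs.items():
            rows.append({"probe_id": pid, "category": "length", "detail": str(sign)})
        for pid in self.detection_fail_ids:
            rows.append({"probe_id": pid, "category": "detection_fail", "detail": ""})
        for pid in self.bead_fail_ids:
            rows.append({"probe_id": pid, "category": "bead_fail", "detail": ""})
        pd.DataFrame(rows, columns=["probe_id", "category", "detail"]).to_csv(
            path, sep="\t", index=False
        )


def _feature_assignments(config: SimulationConfig) -> pd.DataFrame:
    """Patient x feature table of present/absent/NaN, deterministic per seed."""
    patients = _patient_ids(config.n_patients)
    data = {}
    for idx, spec in enumerate(config.feature_specs):
        n_pos, n_abs, n_na = spec.counts(config.n_patients, config.na_fraction)
        order = _rng(config, 20, idx).permutation(config.n_patients)
        col = np.empty(config.n_patients, dtype=object)
        col[order[:n_pos]] = PRESENT
        col[order[n_pos : n_pos + n_abs]] = ABSENT
        col[order[n_pos + n_abs :]] = np.nan
        data[spec.name] = col
    return pd.DataFrame(data, index=pd.Index(patients, name="patient"))


def _rete_lengths(config: SimulationConfig) -> pd.Series:
    lo, hi = config.length_range_um
    vals = _rng(config, 21).uniform(lo, hi, config.n_patients)
    return pd.Series(vals, index=pd.Index(_patient_ids(config.n_patients), name="patient"),
                     name="rete_peg_length_um")


def simulate_histopathology(config: SimulationConfig) -> HistoFeatureTable:
    """Binary feature table plus uniform rete-peg lengths for the cohort."""
    config.validate()
    if not config.feature_specs:
        raise ConfigurationError("feature_specs must be nonempty")
    return HistoFeatureTable(
        features=_feature_assignments(config),
        rete_peg_length_um=_rete_lengths(config),
    )


# ============================================================== beta matrices
def _baseline_betas(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.baseline_beta_dist == "bimodal":
        low = rng.beta(5.0, 45.0, n)       # mean ~0.10
        high = rng.beta(42.5, 7.5, n)      # mean ~0.85
        return np.where(rng.random(n) < 0.5, low, high)
    a, b = config.baseline_beta_dist
    return rng.beta(a, b, n)


def simulate_paired_beta(
    config: SimulationConfig, annotation: ProbeAnnotation
) -> tuple[BetaMatrix, GroundTruth]:
    """Generate the paired β matrix and its ground truth.

    Spiked probes get an exact ±``delta_beta_effect`` shift of the lesional
    mean on the β scale before M-scale noise is added, so β stays strictly
    inside (0, 1) without clipping; a configuration whose shifted means
    leave (0.02, 0.98) is refused.
    """
    config.validate()
    if len(annotation.probe_ids) != config.n_probes:
        raise ConfigurationError("annotation does not match config.n_probes")
    table = annotation.table
    probe_ids = np.asarray(table.index)

    clean = (
        table["chrom"].isin(AUTOSOMES)
        & table["is_cpg"].astype(bool)
        & ~table["is_control"].astype(bool)
        & ~table["is_polymorphic"].astype(bool)
    ).to_numpy()
    needed = config.n_spiked() + config.n_detection_fail + config.n_bead_fail
    clean_ids = probe_ids[clean]
    if needed > len(clean_ids):
        raise ConfigurationError(
            f"{needed} special probes requested but only {len(clean_ids)} clean probes exist"
        )

    pick = _rng(config, 10).permutation(clean_ids)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = list(pick[cursor : cursor + k])
        cursor += k
        return out

    truth = GroundTruth(
        hyper_ids=take(config.n_dmp_hyper),
        hypo_ids=take(config.n_dmp_hypo),
        feature_unique={
            spec.name: take(spec.n_unique_dmps)
            for spec in config.feature_specs
            if spec.n_unique_dmps
        },
        length_probe_signs={},
        detection_fail_ids=take(config.n_detection_fail),
        bead_fail_ids=take(config.n_bead_fail),
    )
    length_ids = take(config.n_length_probes)

    # ---------------------------------------------------------- baselines
    rng_base = _rng(config, 11)
    beta0 = _baseline_betas(config, config.n_probes, rng_base)
    pos_of = {pid: i for i, pid in enumerate(probe_ids)}
    delta = config.delta_beta_effect
    idx_hyper = np.array([pos_of[p] for p in truth.hyper_ids], dtype=int)
    idx_hypo = np.array([pos_of[p] for p in truth.hypo_ids], dtype=int)
    beta0[idx_hyper] = rng_base.uniform(DRAW_LOW, DRAW_HIGH - delta, idx_hyper.size)
    beta0[idx_hypo] = rng_base.uniform(DRAW_LOW + delta, DRAW_HIGH, idx_hypo.size)
    feature_idx = {}
    for spec in config.feature_specs:
        ids = truth.feature_unique.get(spec.name, [])
        idx = np.array([pos_of[p] for p in ids], dtype=int)
        feature_idx[spec.name] = idx
        beta0[idx] = rng_base.uniform(DRAW_LOW, DRAW_HIGH - spec.effect_size, idx.size)

    # ------------------------------------------------------- length probes
    lengths = _rete_lengths(config)
    mid = float(np.mean(config.length_range_um))
    rng_len = _rng(config, 12)
    idx_length = np.array([pos_of[p] for p in length_ids], dtype=int)
    signs = np.where(rng_len.random(idx_length.size) < 0.5, 1, -1)
    jitter = rng_len.uniform(-0.05, 0.05, idx_length.size)
    truth.length_probe_signs = {pid: int(s) for pid, s in zip(length_ids, signs)}
    beta0[idx_length] = 0.5 + jitter  # lesional target varies around this level

    truth.assert_disjoint()

    # ------------------------------------------------- per-tissue target means
    patients = _patient_ids(config.n_patients)
    n_pat = config.n_patients
    target_normal = np.repeat(beta0[:, None], n_pat, axis=1)
    target_disease = target_normal.copy()
    target_disease[idx_hyper] += delta
    target_disease[idx_hypo] -= delta
    assignments = _feature_assignments(config)
    for spec in config.feature_specs:
        idx = feature_idx.get(spec.name, np.array([], dtype=int))
        if idx.size == 0:
            continue
        positive = (assignments[spec.name] == PRESENT).to_numpy()
        target_disease[np.ix_(idx, np.flatnonzero(positive))] += spec.effect_size
    if idx_length.size:
        L = lengths.to_numpy()
        shift = signs[:, None] * config.length_slope * (L[None, :] - mid)
        target_disease[idx_length] = beta0[idx_length, None] + shift

    for name, grid in (("normal", target_normal), ("disease", target_disease)):
        spiked_rows = np.concatenate(
            [idx_hyper, idx_hypo, idx_length]
            + [v for v in feature_idx.values()]
        ).astype(int)
        if spiked_rows.size:
            sub = grid[spiked_rows]
            if (sub <= SAFE_LOW).any() or (sub >= SAFE_HIGH).any():
                raise ConfigurationError(
                    f"spiked {name} mean leaves ({SAFE_LOW}, {SAFE_HIGH}); "
                    "reduce the effect or the slope"
                )

    # ------------------------------------------------------------- sampling
    batch_names = [f"B{i + 1}" for i in range(config.n_batches)]
    patient_batch = {
        pat: batch_names[min(i * config.n_batches // n_pat, config.n_batches - 1)]
        for i, pat in enumerate(patients)
    }
    truth.batch_offsets = dict(zip(batch_names, config.batch_offsets_m))

    patient_effect = _rng(config, 13).normal(0.0, config.patient_sd, n_pat)

    sample_ids, sample_rows = [], []
    for pat in patients:
        for tissue, suffix in ((DISEASE, "D"), (NORMAL, "N")):
            sample_ids.append(f"{pat}_{suffix}")
            sample_rows.append(
                {"patient": pat, "tissue": tissue, "batch": patient_batch[pat]}
            )
    samples = pd.DataFrame(sample_rows, index=pd.Index(sample_ids, name="sample_id"))

    rng_noise = _rng(config, 14)
    n_samples = 2 * n_pat
    m_vals = np.empty((config.n_probes, n_samples))
    for j, (sid, row) in enumerate(samples.iterrows()):
        pat_i = patients.index(row["patient"])
        target = target_disease if row["tissue"] == DISEASE else target_normal
        m = beta_to_m(target[:, pat_i])
        m = m + patient_effect[pat_i] + truth.batch_offsets[row["batch"]]
        m_vals[:, j] = m + rng_noise.normal(0.0, config.noise_sd_m, config.n_probes)

    values = pd.DataFrame(m_to_beta(m_vals), index=pd.Index(probe_ids, name="probe_id"),
                          columns=samples.index)

    # --------------------------------------------------------- QC flag grids
    rng_flags = _rng(config, 15)
    detection = pd.DataFrame(False, index=values.index, columns=values.columns)
    bead = pd.DataFrame(False, index=values.index, columns=values.columns)
    n_fail_samples = math.ceil(0.10 * n_samples)
    for pid in truth.detection_fail_ids:
        cols = rng_flags.choice(n_samples, size=n_fail_samples, replace=False)
        detection.loc[pid, values.columns[cols]] = True
    for pid in truth.bead_fail_ids:
        cols = rng_flags.choice(n_samples, size=n_fail_samples, replace=False)
        bead.loc[pid, values.columns[cols]] = True

    matrix = BetaMatrix(values=values, samples=samples,
                        detection_fail=detection, low_bead=bead)
    return matrix, truth


# ================================================================= one-stop
@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: SimulatedAnnotation
    matrix: BetaMatrix
    truth: GroundTruth
    histopathology: HistoFeatureTable


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate annotation, paired β matrix, ground truth and histopathology."""
    ann = simulate_annotation(config)
    matrix, truth = simulate_paired_beta(config, ann.probes)
    histo = simulate_histopathology(config)
    return SimulatedDataset(config=config, annotation=ann, matrix=matrix,
                            truth=truth, histopathology=histo)


def write_dataset(dataset: SimulatedDataset, directory: str | Path) -> None:
    """Serialize a simulated study: TSV matrices/tables plus BED interval sets."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.matrix.to_tsv(directory)
    dataset.annotation.probes.to_tsv(directory / "annotation.tsv")
    dataset.annotation.psors_loci.to_bed(directory / "psors.bed")
    dataset.annotation.cgi_intervals.to_bed(directory / "cgi.bed")
    transcripts_to_tsv(dataset.annotation.transcripts, directory / "transcripts.tsv")
    dataset.histopathology.to_tsv(directory / "histopathology.tsv")
    dataset.truth.to_tsv(directory / "ground_truth.tsv")


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A spike-free configuration (no DMPs, no feature or length effects)."""
    base = SimulationConfig(
        seed=seed, n_dmp_hyper=0, n_dmp_hypo=0, n_length_probes=0,
        feature_specs=cohort_features(n_unique_dmps=0),
    )
    return replace(base, **overrides)
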