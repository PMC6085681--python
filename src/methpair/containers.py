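"""Core in-memory containers: the paired β matrix, probe annotation and
histopathology tables.

All tabular state is held in pandas objects; the thin wrapper classes enforce
the structural invariants the downstream stages rely on (pairing, value
ranges, annotation coverage) and centralise TSV round-tripping.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

DISEASE = "disease"
NORMAL = "normal"
TISSUES = (DISEASE, NORMAL)

#: annotation columns every probe must carry
ANNOTATION_REQUIRED = ("chrom", "pos", "probe_type", "is_cpg", "is_control", "is_polymorphic")

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions with paired metadata.

    Parameters
    ----------
    values
        DataFrame of β values in [0, 1] (NaN = missing), indexed by probe ID
        with one column per sample.
    samples
        Sample sheet indexed by sample ID with columns ``patient``, ``tissue``
        (``disease``/``normal``) and ``batch``. Column order must match
        ``values.columns``.
    detection_fail, low_bead
        Optional boolean grids aligned with ``values``; True marks a failed
        detection call / a low bead count for that probe in that sample.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    detection_fail: pd.DataFrame | None = None
    low_bead: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError("sample sheet index must match value columns, in order")
        missing = {"patient", "tissue", "batch"} - set(self.samples.columns)
        if missing:
            raise ValidationError(f"sample sheet lacks columns: {sorted(missing)}")
        bad_tissue = set(self.samples["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValidationError(f"unknown tissue labels: {sorted(bad_tissue)}")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0:
                raise ValidationError("β values must lie in [0, 1]")
        for name in ("detection_fail", "low_bead"):
            grid = getattr(self, name)
            if grid is not None and (
                list(grid.index) != list(self.values.index)
                or list(grid.columns) != list(self.values.columns)
            ):
                raise ValidationError(f"{name} grid is not aligned with the value matrix")

    # ------------------------------------------------------------------ shape
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def patients(self) -> list:
        """Patients in first-appearance order."""
        return list(dict.fromkeys(self.samples["patient"]))

    # ---------------------------------------------------------------- pairing
    def validate_paired(self) -> None:
        """Require exactly one disease and one normal sample per patient."""
        counts = self.samples.groupby(["patient", "tissue"], sort=False).size()
        for patient in self.patients:
            for tissue in TISSUES:
                if counts.get((patient, tissue), 0) != 1:
                    raise ValidationError(
                        f"patient {patient!r} lacks exactly one {tissue} sample"
                    )

    def paired_views(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (disease, normal) value frames, both probes x patients.

        Columns are relabelled to patient IDs and aligned, so that
        ``disease - normal`` is the per-patient paired difference.
        """
        self.validate_paired()
        patients = self.patients
        out = []
        for tissue in TISSUES:
            sheet = self.samples[self.samples["tissue"] == tissue]
            by_patient = pd.Series(sheet.index, index=sheet["patient"])
            frame = self.values[by_patient.loc[patients].to_numpy()]
            frame.columns = patients
            out.append(frame)
        return out[0], out[1]

    # --------------------------------------------------------------- subsets
    def subset_probes(self, probe_ids) -> "BetaMatrix":
        idx = pd.Index(probe_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise ValidationError(f"unknown probes requested: {list(missing[:5])}")
        return BetaMatrix(
            values=self.values.loc[idx].copy(),
            samples=self.samples.copy(),
            detection_fail=None if self.detection_fail is None else self.detection_fail.loc[idx].copy(),
            low_bead=None if self.low_bead is None else self.low_bead.loc[idx].copy(),
        )

    def subset_patients(self, patients) -> "BetaMatrix":
        keep = self.samples.index[self.samples["patient"].isin(set(patients))]
        return BetaMatrix(
            values=self.values[keep].copy(),
            samples=self.samples.loc[keep].copy(),
            detection_fail=None if self.detection_fail is None else self.detection_fail[keep].copy(),
            low_bead=None if self.low_bead is None else self.low_bead[keep].copy(),
        )

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            values=self.values.copy(),
            samples=self.samples.copy(),
            detection_fail=None if self.detection_fail is None else self.detection_fail.copy(),
            low_bead=None if self.low_bead is None else self.low_bead.copy(),
        )

    # -------------------------------------------------------------------- io
    def to_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(directory / "beta.tsv", sep="\t", index_label="probe_id")
        self.samples.to_csv(directory / "samples.tsv", sep="\t", index_label="sample_id")
        if self.detection_fail is not None:
            self.detection_fail.astype(int).to_csv(
                directory / "detection_fail.tsv", sep="\t", index_label="probe_id"
            )
        if self.low_bead is not None:
            self.low_bead.astype(int).to_csv(
                directory / "low_bead.tsv", sep="\t", index_label="probe_id"
            )

    @classmethod
    def from_tsv(cls, directory: str | Path) -> "BetaMatrix":
        directory = Path(directory)
        values = pd.read_csv(directory / "beta.tsv", sep="\t", index_col="probe_id")
        samples = pd.read_csv(directory / "samples.tsv", sep="\t", index_col="sample_id")
        flags = {}
        for attr, fname in (("detection_fail", "detection_fail.tsv"), ("low_bead", "low_bead.tsv")):
            path = directory / fname
            if path.exists():
                flags[attr] = pd.read_csv(path, sep="\t", index_col="probe_id").astype(bool)
        return cls(values=values, samples=samples, **flags)


@dataclass
class ProbeAnnotation:
    """Per-probe genomic metadata (coordinates, design type, flags, classes).

    ``table`` is indexed by probe ID. Required columns: chrom, pos,
    probe_type (``I``/``II``), is_cpg, is_control, is_polymorphic. Optional
    columns produced by the generator or the annotation engine: region_class,
    cgi_relation, in_repeat, gene.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(ANNOTATION_REQUIRED) - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation lacks columns: {sorted(missing)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def require(self, probe_ids) -> pd.DataFrame:
        """Return rows for ``probe_ids``; hard error naming any missing probe."""
        idx = pd.Index(probe_ids)
        missing = idx.difference(self.table.index)
        if len(missing):
            raise ValidationError(f"annotation missing for probe(s): {list(missing[:5])}")
        return self.table.loc[idx]

    def on_sex_chrom(self) -> pd.Series:
        return self.table["chrom"].isin(SEX_CHROMS)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeAnnotation":
        return cls(pd.read_csv(path, sep="\t", index_col="probe_id"))


PRESENT = "present"
ABSENT = "absent"


@dataclass
class HistoFeatureTable:
    """Per-patient binary histopathology features and rete-peg length.

    ``features`` is indexed by patient; each feature column holds
    ``present``/``absent``/NaN. ``rete_peg_length_um`` holds the maximum
    rete-peg length per biopsy in µm (NaN = not measured).
    """

    features: pd.DataFrame
    rete_peg_length_um: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        allowed = {PRESENT, ABSENT}
        for col in self.features.columns:
            vals = set(self.features[col].dropna())
            if not vals <= allowed:
                raise ValidationError(f"feature {col!r} has values outside present/absent/NA")
        if self.rete_peg_length_um is None:
            self.rete_peg_length_um = pd.Series(np.nan, index=self.features.index)
        lengths = self.rete_peg_length_um.dropna()
        if (lengths <= 0).any():
            raise ValidationError("rete-peg lengths must be positive")

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def patients(self) -> pd.Index:
        return self.features.index

    def feature_groups(self, feature: str) -> tuple[list, list]:
        """(present patients, absent patients); missing values drop the patient."""
        if feature not in self.features.columns:
            raise ValidationError(f"unknown histopathology feature {feature!r}")
        col = self.features[feature]
        return list(col.index[col == PRESENT]), list(col.index[col == ABSENT])

    def to_tsv(self, path: str | Path) -> None:
        out = self.features.copy()
        out = out.replace({PRESENT: "P", ABSENT: "A"}).fillna("NA")
        out["rete_peg_length_um"] = self.rete_peg_length_um
        out.to_csv(path, sep="\t", index_label="patient")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HistoFeatureTable":
        raw = pd.read_csv(path, sep="\t", index_col="patient")
        lengths = raw.pop("rete_peg_length_um")
        feats = raw.replace({"P": PRESENT, "A": ABSENT, "NA": np.nan})
        return cls(features=feats, rete_peg_length_um=lengths)
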