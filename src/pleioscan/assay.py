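"""Core data containers: protein assays, participant records and cohorts.

A :class:`Cohort` bundles a participant table (one row per subject) with a
panel of :class:`ProteinAssay` objects aligned to the participant order.
NPX values live on a log2 scale and may be negative; a one-unit increase
corresponds to a doubling of the underlying protein concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import DataError, SchemaError

#: column order of the on-disk participant table
PARTICIPANT_COLUMNS = (
    "participant_id",
    "statin_use",
    "age",
    "sex",
    "bmi",
    "systolic_bp",
    "alcohol",
    "diabetes",
    "smoking",
    "physical_activity",
    "education",
    "hypertension",
    "myocardial_infarction",
    "stroke",
    "cancer",
)

CONTINUOUS_COVARIATES = ("age", "bmi", "systolic_bp", "alcohol")

#: declared levels for every categorical covariate (first level = reference)
CATEGORICAL_LEVELS = {
    "sex": ("male", "female"),
    "smoking": ("never", "previous", "current"),
    "physical_activity": ("little_or_not", "irregular_1h", "regular_1h", "regular_2h"),
    "education": ("low", "middle", "high"),
}

BINARY_FLAGS = ("diabetes", "hypertension", "myocardial_infarction", "stroke", "cancer")


@dataclass
class ParticipantRecord:
    """One study participant; invalid field values raise on construction."""

    participant_id: str
    statin_use: int
    age: float
    sex: str
    bmi: float
    systolic_bp: float
    alcohol: float
    diabetes: int
    smoking: str
    physical_activity: str
    education: str
    hypertension: Optional[int] = None
    myocardial_infarction: Optional[int] = None
    stroke: Optional[int] = None
    cancer: Optional[int] = None

    def __post_init__(self) -> None:
        for name, lo in (("age", 0.0), ("bmi", 0.0), ("systolic_bp", 0.0)):
            v = getattr(self, name)
            if v is not None and not (np.isnan(v) or v > lo):
                raise DataError(f"{name} must be > {lo}, got {v!r}")
        if self.alcohol is not None and not (np.isnan(self.alcohol) or self.alcohol >= 0):
            raise DataError(f"alcohol must be >= 0, got {self.alcohol!r}")
        for name, levels in CATEGORICAL_LEVELS.items():
            v = getattr(self, name)
            if v is not None and not (isinstance(v, float) and np.isnan(v)) and v not in levels:
                raise DataError(f"{name} level {v!r} not in declared levels {levels}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ProteinAssay:
    """A single protein's NPX vector plus assay-level metadata.

    ``below_lod_mask`` is true exactly where the pre-imputation value fell
    strictly below ``lod``; it is preserved through imputation for provenance.
    """

    protein_name: str
    values: np.ndarray
    lod: float = float("-inf")
    below_lod_mask: Optional[np.ndarray] = None
    inter_assay_cv: float = float("nan")
    duplicate_group: Optional[str] = None
    modified_idx: Optional[np.ndarray] = None  # indices altered by outlier injection

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.below_lod_mask is None:
            self.below_lod_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.below_lod_mask = np.asarray(self.below_lod_mask, dtype=bool)
            if self.below_lod_mask.shape != self.values.shape:
                raise DataError(
                    f"below_lod_mask length {self.below_lod_mask.size} != "
                    f"values length {self.values.size} for {self.protein_name}"
                )

    def copy(self) -> "ProteinAssay":
        return replace(
            self,
            values=self.values.copy(),
            below_lod_mask=self.below_lod_mask.copy(),
            modified_idx=None if self.modified_idx is None else self.modified_idx.copy(),
        )

    @property
    def n(self) -> int:
        return self.values.size

    def below_lod_fraction(self) -> float:
        """Fraction below LOD among non-missing values; NaN if all missing."""
        ok = ~np.isnan(self.values)
        if not ok.any():
            return float("nan")
        return float(self.below_lod_mask[ok].mean())


@dataclass
class Cohort:
    """One study arm: participants, protein panel and (optionally) the
    generating truth for synthetic cohorts."""

    study_label: str
    participants: pd.DataFrame
    panel: list[ProteinAssay] = field(default_factory=list)
    truth: Optional[dict[str, float]] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in PARTICIPANT_COLUMNS if c not in self.participants.columns]
        if missing:
            raise SchemaError(f"participant table missing columns: {missing}")
        ids = self.participants["participant_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise DataError(f"duplicate participant_ids: {dupes[:5]}")
        n = len(self.participants)
        for assay in self.panel:
            if assay.n != n:
                raise DataError(
                    f"assay {assay.protein_name} has {assay.n} values for {n} participants"
                )

    @property
    def n(self) -> int:
        return len(self.participants)

    def iter_records(self) -> Iterator[ParticipantRecord]:
        for _, row in self.participants.iterrows():
            yield ParticipantRecord(**{k: row[k] for k in PARTICIPANT_COLUMNS})

    def assay(self, protein_name: str) -> ProteinAssay:
        for a in self.panel:
            if a.protein_name == protein_name:
                return a
        raise KeyError(protein_name)

    def npx_matrix(self) -> pd.DataFrame:
        """Wide NPX matrix indexed like the participant table."""
        data = {a.protein_name: a.values for a in self.panel}
        return pd.DataFrame(data, index=self.participants["participant_id"].to_numpy())


# ---------------------------------------------------------------------------
# plain-text serialization (TSV + JSON)
# ---------------------------------------------------------------------------

def write_participants(cohort: Cohort, path: str | Path) -> None:
    df = cohort.participants.loc[:, list(PARTICIPANT_COLUMNS)]
    df.to_csv(path, sep="\t", index=False, na_rep="")


def write_panel(cohort: Cohort, matrix_path: str | Path, meta_path: str | Path) -> None:
    mat = cohort.npx_matrix().reset_index(names="participant_id")
    mat.to_csv(matrix_path, sep="\t", index=False, na_rep="")
    meta = pd.DataFrame(
        {
            "protein_name": [a.protein_name for a in cohort.panel],
            "lod": [a.lod for a in cohort.panel],
            "inter_assay_cv": [a.inter_assay_cv for a in cohort.panel],
            "duplicate_group": [a.duplicate_group or "" for a in cohort.panel],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False, na_rep="")


def write_truth(cohort: Cohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.truth or {}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_cohort(
    participants_path: str | Path,
    matrix_path: str | Path,
    meta_path: str | Path,
    study_label: str = "cohort",
) -> Cohort:
    participants = pd.read_csv(
        participants_path,
        sep="\t",
        dtype={"participant_id": str},
        keep_default_na=True,
    )
    missing = [c for c in PARTICIPANT_COLUMNS if c not in participants.columns]
    if missing:
        raise SchemaError(f"{participants_path}: missing columns {missing}")
    mat = pd.read_csv(matrix_path, sep="\t", dtype={"participant_id": str})
    if "participant_id" not in mat.columns:
        raise SchemaError(f"{matrix_path}: missing participant_id column")
    if not mat["participant_id"].equals(participants["participant_id"]):
        mat = mat.set_index("participant_id").reindex(participants["participant_id"]).reset_index()
    meta = pd.read_csv(meta_path, sep="\t").set_index("protein_name")
    panel = []
    for name in mat.columns:
        if name == "participant_id":
            continue
        lod = float(meta.at[name, "lod"]) if name in meta.index else float("-inf")
        cv = float(meta.at[name, "inter_assay_cv"]) if name in meta.index else float("nan")
        group = None
        if name in meta.index:
            g = meta.at[name, "duplicate_group"]
            if isinstance(g, str) and g:
                group = g
        values = mat[name].to_numpy(dtype=float)
        mask = values < lod
        panel.append(
            ProteinAssay(
                protein_name=name,
                values=values,
                lod=lod,
                below_lod_mask=mask,
                inter_assay_cv=cv,
                duplicate_group=group,
            )
        )
    return Cohort(study_label=study_label, participants=participants, panel=panel)


def read_olink_long(path: str | Path) -> pd.DataFrame:
    """Map an Olink long-format NPX export (SampleID, Assay, NPX, LOD) to the
    internal wide matrix; returns a DataFrame with participant_id first."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"SampleID", "Assay", "NPX"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: long NPX export needs columns {sorted(required)}")
    wide = df.pivot(index="SampleID", columns="Assay", values="NPX")
    wide.index.name = "participant_id"
    return wide.reset_index()
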