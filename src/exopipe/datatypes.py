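"""Core data containers for the exo-miRNA RT-qPCR pipeline.

The pipeline operates on threshold-cycle (CT) matrices from two-timepoint
liquid biopsies (one plasma sample at disease onset, one at the end of
induction chemotherapy, per patient), a clinical annotation table, and a
literature-curated list linking miRNA modulation direction to
chemoresistance for each drug of the induction regimen.

Sample identifiers follow the convention ``"<patient_id>:<timepoint>"``
with timepoint in ``{"onset", "end"}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TIMEPOINTS = ("onset", "end")
DRUGS = (
    "cisplatin",
    "etoposide",
    "doxorubicin",
    "vincristine",
    "carboplatin",
    "cyclophosphamide",
)
DIRECTIONS = ("up", "down")

#: drugs whose chemoresistance index drives the poor-responder cluster label
PROGNOSTIC_DRUGS = ("carboplatin", "cisplatin", "doxorubicin")


def make_sample_id(patient_id: str, timepoint: str) -> str:
    if timepoint not in TIMEPOINTS:
        raise ValueError(
            f"unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}"
        )
    return f"{patient_id}:{timepoint}"


def split_sample_id(sample_id: str) -> tuple[str, str]:
    """Split ``"P01:onset"`` into ``("P01", "onset")``."""
    patient, sep, timepoint = sample_id.rpartition(":")
    if not sep or timepoint not in TIMEPOINTS:
        raise ValueError(
            f"sample id {sample_id!r} does not follow '<patient>:<timepoint>' "
            f"with timepoint in {TIMEPOINTS}"
        )
    return patient, timepoint


def canonical_mirna(name: str) -> str:
    """Canonical key for miRNA name matching.

    Assay exports and published tables mix dialects ("hsa-miR-29c",
    "miR-29c", "hsa-mir-29c"); matching is case-insensitive with the
    species prefix stripped.
    """
    key = name.strip().lower()
    if key.startswith("hsa-"):
        key = key[4:]
    return key


@dataclass
class CTMatrix:
    """Raw threshold-cycle values, samples x miRNAs.

    ``ct`` is a float DataFrame indexed by sample id with one column per
    assay; failed/undetermined wells are NaN.  Present values must be
    finite and positive (a CT is a PCR cycle count).
    """

    ct: pd.DataFrame

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        if self.ct.index.has_duplicates:
            dup = self.ct.index[self.ct.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.ct.columns.has_duplicates:
            dup = self.ct.columns[self.ct.columns.duplicated()][0]
            raise ValueError(f"duplicate miRNA {dup!r}")
        for s in self.ct.index:
            split_sample_id(s)  # validates the timepoint label
        vals = self.ct.to_numpy()
        present = ~np.isnan(vals)
        if np.any(~np.isfinite(vals[present])) or np.any(vals[present] <= 0):
            raise ValueError("present CT values must be finite and positive")

    @property
    def samples(self) -> list[str]:
        return list(self.ct.index)

    @property
    def mirnas(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(split_sample_id(s)[0])
        return list(seen)

    def timepoint_of(self, sample_id: str) -> str:
        return split_sample_id(sample_id)[1]

    def n_missing(self) -> int:
        return int(self.ct.isna().sum().sum())

    def copy(self) -> "CTMatrix":
        return CTMatrix(self.ct.copy())


@dataclass
class NormalizedMatrix:
    """Global-mean normalized expression (ΔCT scale, log2 units).

    ΔCT = CT − (sample's mean CT over detected assays); lower ΔCT means
    higher relative expression.  ``detected`` marks wells whose raw CT
    fell strictly below the detection ceiling; ``imputed`` marks wells
    filled in afterwards.  A well is never both detected and imputed.
    """

    delta_ct: pd.DataFrame
    detected: pd.DataFrame
    imputed: pd.DataFrame

    def __post_init__(self) -> None:
        self.delta_ct = self.delta_ct.astype(float)
        self.detected = self.detected.astype(bool)
        self.imputed = self.imputed.astype(bool)
        for other in (self.detected, self.imputed):
            if not (
                other.index.equals(self.delta_ct.index)
                and other.columns.equals(self.delta_ct.columns)
            ):
                raise ValueError("masks must share the ΔCT matrix's axes")
        both = (self.detected & self.imputed).to_numpy()
        if both.any():
            raise ValueError("a well cannot be both detected and imputed")
        known = (self.detected | self.imputed).to_numpy()
        if np.any(~np.isfinite(self.delta_ct.to_numpy()[known])):
            raise ValueError("ΔCT must be finite wherever detected or imputed")

    @property
    def samples(self) -> list[str]:
        return list(self.delta_ct.index)

    @property
    def mirnas(self) -> list[str]:
        return list(self.delta_ct.columns)

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(split_sample_id(s)[0])
        return list(seen)

    def samples_at(self, timepoint: str) -> list[str]:
        return [s for s in self.samples if split_sample_id(s)[1] == timepoint]

    def copy(self) -> "NormalizedMatrix":
        return NormalizedMatrix(
            self.delta_ct.copy(), self.detected.copy(), self.imputed.copy()
        )


CLINICAL_COLUMNS = [
    "patient_id",
    "inss_stage",
    "mycn",
    "induction_response",
    "relapse",
    "efs_time",
    "efs_event",
    "origin",
    "age",
]

INSS_STAGES = ("3", "4", "4S")
MYCN_LEVELS = ("AMPL", "NO AMPL", "NA")
RESPONSE_LEVELS = ("MR", "PR", "VGPR", "NA")


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a clinical annotation table.

    Columns: patient_id, inss_stage (3/4/4S), mycn (AMPL/NO AMPL/NA),
    induction_response (MR/PR/VGPR/NA), relapse (yes/no), efs_time
    (months, >= 0), efs_event (0/1), origin (center label), age (months,
    optional).  Returns a copy indexed by patient_id.
    """
    missing = [c for c in CLINICAL_COLUMNS[:-1] if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns {missing}")
    df = clinical.copy()
    if "age" not in df.columns:
        df["age"] = np.nan
    df["patient_id"] = df["patient_id"].astype(str)
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient_id {dup!r} in clinical table")
    df["inss_stage"] = df["inss_stage"].astype(str)
    bad = set(df["inss_stage"]) - set(INSS_STAGES)
    if bad:
        raise ValueError(f"unknown INSS stage labels {sorted(bad)}")
    for col, levels in (("mycn", MYCN_LEVELS), ("induction_response", RESPONSE_LEVELS)):
        df[col] = df[col].fillna("NA").astype(str)
        bad = set(df[col]) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} labels {sorted(bad)}")
    df["relapse"] = df["relapse"].astype(str).str.lower()
    bad = set(df["relapse"]) - {"yes", "no"}
    if bad:
        raise ValueError(f"relapse must be yes/no, got {sorted(bad)}")
    df["efs_time"] = df["efs_time"].astype(float)
    if (df["efs_time"] < 0).any():
        raise ValueError("efs_time must be nonnegative")
    df["efs_event"] = df["efs_event"].astype(int)
    if not set(df["efs_event"]) <= {0, 1}:
        raise ValueError("efs_event must be 0/1")
    df["age"] = df["age"].astype(float)
    return df.set_index("patient_id", drop=False)


@dataclass(frozen=True)
class ChemoresistanceEntry:
    mirna: str
    drug: str
    direction: str


@dataclass
class ChemoresistanceList:
    """Literature-curated (miRNA, drug, direction) resistance associations.

    ``direction`` is the modulation ("up" or "down") reported to promote
    resistance to that drug; (miRNA, drug) pairs are unique.
    """

    entries: list[ChemoresistanceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if e.drug not in DRUGS:
                raise ValueError(f"unknown drug {e.drug!r}; expected one of {DRUGS}")
            if e.direction not in DIRECTIONS:
                raise ValueError(
                    f"direction must be 'up' or 'down', got {e.direction!r}"
                )
            key = (canonical_mirna(e.mirna), e.drug)
            if key in seen:
                raise ValueError(f"duplicate (miRNA, drug) entry {key}")
            seen.add(key)

    @property
    def mirnas(self) -> list[str]:
        seen: dict[str, str] = {}
        for e in self.entries:
            seen.setdefault(canonical_mirna(e.mirna), e.mirna)
        return list(seen.values())

    def by_drug(self, drug: str) -> dict[str, str]:
        """Map canonical miRNA key -> resistance direction for one drug."""
        if drug not in DRUGS:
            raise ValueError(f"unknown drug {drug!r}")
        return {
            canonical_mirna(e.mirna): e.direction
            for e in self.entries
            if e.drug == drug
        }

    def drugs_with_entries(self) -> list[str]:
        return [d for d in DRUGS if self.by_drug(d)]


@dataclass
class AnalysisConfig:
    """Pipeline-wide analysis settings with the study's defaults.

    ct_min/ct_max bound the reliable CT window (values outside are treated
    as experiment failures); ct_max doubles as the detection ceiling.
    detection_fraction is the minimum fraction of samples in which an
    assay must be detected to survive filtering.  fc_threshold_log2 is the
    |−ΔΔCT| significance magnitude (log2 of linear 1.5).
    """

    ct_min: float = 14.0
    ct_max: float = 32.0
    detection_fraction: float = 0.80
    fc_threshold_log2: float = 0.58
    alpha: float = 0.05
    elasticnet_mixing: float = 0.7
    wapv_batch_threshold: float = 0.05
    kmeans_k: int = 2
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.detection_fraction <= 1):
            raise ValueError("detection_fraction must be in (0, 1]")
        if self.ct_min >= self.ct_max:
            raise ValueError("ct_min must be < ct_max")
        for name in ("fc_threshold_log2", "alpha", "wapv_batch_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.elasticnet_mixing <= 1):
            raise ValueError("elasticnet_mixing must be in (0, 1]")
        if self.kmeans_k < 1:
            raise ValueError("kmeans_k must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**{k: v for k, v in mapping.items()})  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, object]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
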