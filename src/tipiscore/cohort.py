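"""Clinical cohort domain types and tabular I/O.

A cohort is an ordered collection of pretreatment patient records for
HER2-positive breast cancer treated with neoadjuvant chemotherapy plus dual
anti-HER2 blockade.  Each record carries the core-biopsy pathology variables
(Ki-67 labelling index, stromal TIL percentage, Nottingham grade), baseline
complete-blood-count values, clinical covariates, and the binary pathological
complete response (pCR, ypT0/is ypN0) outcome.

The interchange format is comma-delimited UTF-8 with a header row, decimal
points, and booleans encoded as ``{0,1}``.  Blood counts are interpreted in
units of 1e9 cells per litre (the usual scale in the systemic
immune-inflammation index literature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "summarize_baseline",
    "MENOPAUSAL_LEVELS",
    "CLINICAL_T_LEVELS",
    "CLINICAL_N_LEVELS",
    "CLINICAL_STAGE_LEVELS",
    "HR_LEVELS",
    "HER2_LEVELS",
]

MENOPAUSAL_LEVELS = ("premenopausal", "postmenopausal")
CLINICAL_T_LEVELS = ("cT1", "cT2", "cT3_4")
CLINICAL_N_LEVELS = ("cN0", "cN1", "cN2_3")
CLINICAL_STAGE_LEVELS = ("IIA", "IIB", "III")
HR_LEVELS = ("negative", "positive")
HER2_LEVELS = ("IHC3plus", "IHC2plus_ISHpos")


class CohortValidationError(ValueError):
    """A record (or the cohort as a whole) violates a domain invariant."""


class SchemaError(ValueError):
    """The input file does not expose a required column."""


_REQUIRED_COLUMNS = (
    "patient_id",
    "age_years",
    "menopausal_status",
    "clinical_t",
    "clinical_n",
    "clinical_stage",
    "hr_status",
    "her2_category",
    "grade",
    "ki67_percent",
    "stromal_tils_percent",
    "neutrophils",
    "lymphocytes",
    "platelets",
    "pcr",
)
_OPTIONAL_COLUMNS = ("tumor_size_mm",)

_CONTINUOUS_FIELDS = (
    "age_years",
    "tumor_size_mm",
    "ki67_percent",
    "stromal_tils_percent",
    "neutrophils",
    "lymphocytes",
    "platelets",
)
_CATEGORICAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "menopausal_status": MENOPAUSAL_LEVELS,
    "clinical_t": CLINICAL_T_LEVELS,
    "clinical_n": CLINICAL_N_LEVELS,
    "clinical_stage": CLINICAL_STAGE_LEVELS,
    "hr_status": HR_LEVELS,
    "her2_category": HER2_LEVELS,
}


@dataclass(frozen=True)
class PatientRecord:
    """One patient's pretreatment pathology, blood counts, clinical covariates and pCR outcome.

    Blood counts (``neutrophils``, ``lymphocytes``, ``platelets``) are in
    1e9 cells/L.  ``ki67_percent`` and ``stromal_tils_percent`` are percentages
    in [0, 100]; ``grade`` is the Nottingham histologic grade (1-3).
    ``tumor_size_mm`` may be missing (``None``).
    """

    patient_id: str
    age_years: float
    menopausal_status: str
    clinical_t: str
    clinical_n: str
    clinical_stage: str
    hr_status: str
    her2_category: str
    grade: int
    ki67_percent: float
    stromal_tils_percent: float
    neutrophils: float
    lymphocytes: float
    platelets: float
    pcr: bool
    tumor_size_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("patient_id must be a non-empty string")
        if not (self.age_years > 0 and math.isfinite(self.age_years)):
            raise CohortValidationError(
                f"record {self.patient_id!r}: age_years must be positive, got {self.age_years!r}"
            )
        for name, levels in _CATEGORICAL_LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise CohortValidationError(
                    f"record {self.patient_id!r}: {name} must be one of {levels}, got {value!r}"
                )
        if self.grade not in (1, 2, 3):
            raise CohortValidationError(
                f"record {self.patient_id!r}: grade must be in {{1,2,3}}, got {self.grade!r}"
            )
        for name in ("ki67_percent", "stromal_tils_percent"):
            value = getattr(self, name)
            if not (0.0 <= value <= 100.0):
                raise CohortValidationError(
                    f"record {self.patient_id!r}: {name} must lie in [0, 100], got {value!r}"
                )
        for name in ("neutrophils", "lymphocytes", "platelets"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise CohortValidationError(
                    f"record {self.patient_id!r}: {name} must be strictly positive, got {value!r}"
                )
        if self.tumor_size_mm is not None and not self.tumor_size_mm > 0:
            raise CohortValidationError(
                f"record {self.patient_id!r}: tumor_size_mm must be positive when present"
            )
        if not isinstance(self.pcr, bool):
            raise CohortValidationError(
                f"record {self.patient_id!r}: pcr must be boolean, got {self.pcr!r}"
            )


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of validated patient records with a provenance tag."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def require_nonempty(self, operation: str = "analysis") -> None:
        if not self.records:
            raise CohortValidationError(f"{operation} requires a non-empty cohort")

    def to_dataframe(self) -> pd.DataFrame:
        """Cohort as a pandas DataFrame, one row per record, order preserved."""
        rows = []
        for r in self.records:
            row = {f.name: getattr(r, f.name) for f in fields(PatientRecord)}
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "Cohort":
        records = []
        for idx, row in df.iterrows():
            records.append(_record_from_row(row, idx))
        return cls(records=tuple(records), provenance=provenance)


def _parse_bool(value: object, row: object, name: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str) and value.strip() in ("0", "1"):
        return value.strip() == "1"
    if isinstance(value, (float, np.floating)) and value in (0.0, 1.0):
        return bool(value)
    raise CohortValidationError(f"row {row}: {name} must be encoded as 0/1, got {value!r}")


def _record_from_row(row: Mapping[str, object], idx: object) -> PatientRecord:
    def _float(name: str) -> float:
        try:
            return float(row[name])  # type: ignore[arg-type]
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(f"row {idx}: cannot parse {name}={row[name]!r}") from exc

    size = row.get("tumor_size_mm") if hasattr(row, "get") else row["tumor_size_mm"]
    tumor_size = None
    if size is not None and not (isinstance(size, float) and math.isnan(size)) and size != "":
        tumor_size = float(size)  # type: ignore[arg-type]
    try:
        grade = int(row["grade"])  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise CohortValidationError(f"row {idx}: cannot parse grade={row['grade']!r}") from exc
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        age_years=_float("age_years"),
        menopausal_status=str(row["menopausal_status"]),
        clinical_t=str(row["clinical_t"]),
        clinical_n=str(row["clinical_n"]),
        clinical_stage=str(row["clinical_stage"]),
        hr_status=str(row["hr_status"]),
        her2_category=str(row["her2_category"]),
        grade=grade,
        ki67_percent=_float("ki67_percent"),
        stromal_tils_percent=_float("stromal_tils_percent"),
        neutrophils=_float("neutrophils"),
        lymphocytes=_float("lymphocytes"),
        platelets=_float("platelets"),
        pcr=_parse_bool(row["pcr"], idx, "pcr"),
        tumor_size_mm=tumor_size,
    )


def read_cohort(
    path: str,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> Cohort:
    """Read a cohort CSV, validating every row against the record invariants.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from canonical field names to the column names used
        in the file (e.g. ``{"ki67_percent": "KI67"}``).  Unmapped fields are
        looked up under their canonical names.
    provenance
        Provenance tag for the cohort; defaults to ``"file:<path>"``.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "tumor_size_mm" not in df.columns:
        df = df.assign(tumor_size_mm=np.nan)
    return Cohort.from_dataframe(df, provenance=provenance if provenance is not None else f"file:{path}")


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write a cohort to CSV.

    Continuous fields are written with 6-decimal precision; booleans as 0/1.
    ``read_cohort(write_cohort(c))`` reproduces ``c`` field for field.
    """
    cohort.require_nonempty("write_cohort")
    df = cohort.to_dataframe().copy()
    df["pcr"] = df["pcr"].astype(int)
    for name in _CONTINUOUS_FIELDS:
        df[name] = df[name].map(lambda v: "" if pd.isna(v) else f"{float(v):.6f}")
    df.to_csv(path, index=False)


# Variables summarised in the baseline table, with their display levels.
_BASELINE_CATEGORICALS: Mapping[str, Sequence[str]] = {
    "menopausal_status": MENOPAUSAL_LEVELS,
    "clinical_t": CLINICAL_T_LEVELS,
    "clinical_n": CLINICAL_N_LEVELS,
    "clinical_stage": CLINICAL_STAGE_LEVELS,
    "hr_status": HR_LEVELS,
    "her2_category": HER2_LEVELS,
    "grade": ("1", "2", "3"),
    "ki67_category": ("le20", "gt20"),
    "tils_category": ("low", "intermediate", "high"),
}

KI67_CATEGORY_THRESHOLD = 20.0  # descriptive <=20% / >20% split


def ki67_category(value: float) -> str:
    return "le20" if value <= KI67_CATEGORY_THRESHOLD else "gt20"


def tils_category(value: float) -> str:
    """Stromal TILs category: low (<10%), intermediate (10-40%), high (>40%)."""
    if value < 10.0:
        return "low"
    if value <= 40.0:
        return "intermediate"
    return "high"


def summarize_baseline(cohort: Cohort) -> pd.DataFrame:
    """Per-variable baseline summaries overall and stratified by pCR.

    Continuous variables get mean, SD, median and range (SD is reported as 0
    for a single observation, pandas' ddof=1 NaN being replaced); categorical
    variables get counts with column percentages, overall and within each pCR
    stratum.  Rows with a missing optional field are excluded listwise from
    that variable's summary only.
    """
    cohort.require_nonempty("summarize_baseline")
    df = cohort.to_dataframe()
    df["ki67_category"] = df["ki67_percent"].map(ki67_category)
    df["tils_category"] = df["stromal_tils_percent"].map(tils_category)
    df["grade"] = df["grade"].astype(str)
    n = len(df)
    n_pcr = int(df["pcr"].sum())
    rows: list[dict[str, object]] = [
        {
            "variable": "pcr",
            "level": "overall",
            "kind": "outcome",
            "count": n_pcr,
            "percent": 100.0 * n_pcr / n,
            "n": n,
        }
    ]
    for name in ("age_years", "tumor_size_mm", "ki67_percent", "stromal_tils_percent"):
        values = df[name].dropna()
        if values.empty:
            continue
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        rows.append(
            {
                "variable": name,
                "level": "",
                "kind": "continuous",
                "mean": float(values.mean()),
                "sd": sd,
                "median": float(values.median()),
                "min": float(values.min()),
                "max": float(values.max()),
                "n": int(len(values)),
            }
        )
    pcr_mask = df["pcr"].astype(bool)
    for name, levels in _BASELINE_CATEGORICALS.items():
        observed = df[name]
        for level in levels:
            count = int((observed == level).sum())
            if count == 0:
                continue
            c_pos = int(((observed == level) & pcr_mask).sum())
            c_neg = count - c_pos
            rows.append(
                {
                    "variable": name,
                    "level": level,
                    "kind": "categorical",
                    "count": count,
                    "percent": 100.0 * count / n,
                    "pcr_pos": c_pos,
                    "pcr_pos_percent": 100.0 * c_pos / count,
                    "pcr_neg": c_neg,
                    "pcr_neg_percent": 100.0 * c_neg / count,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
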