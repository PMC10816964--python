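"""Respondent-level data model and cohort file I/O.

A cohort is a delimited text file with a header, one row per respondent.
Column names match the :class:`RespondentRecord` field names, with the eight
Epworth items as ``ess1`` … ``ess8``.  Booleans are written as 0/1 and
missing optional values as empty cells.  The reference standard is the
apnea–hypopnea index (AHI, events/h) from cardiorespiratory polygraphy and,
optionally, the mean sleep latency of the maintenance of wakefulness test
(MWT, minutes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import pandas as pd

from .exceptions import ValidationError

#: BNSQ frequency scale: 1 = never or less than once per month,
#: 2 = less than once per week, 3 = on 1–2 nights per week,
#: 4 = on 3–5 nights per week, 5 = every night or almost every night.
BNSQ_MIN, BNSQ_MAX = 1, 5

ESS_N_ITEMS = 8
ESS_ITEM_MAX = 3


@dataclass
class RespondentRecord:
    """One driver's questionnaire answers, measurements and outcomes.

    Measured ("visit") BMI and neck circumference are authoritative; the
    questionnaire self-reports are kept alongside so that the published
    questionnaire→visit calibration lines can be applied when a visit value
    is genuinely unavailable.
    """

    id: str
    sex: str  # "male" | "female"
    age_years: float
    bmi_visit: float
    neck_cm_visit: float
    snoring_freq: int
    apnea_freq: int
    hypertension: bool
    ess_items: Sequence[int]
    ahi: float
    bmi_questionnaire: Optional[float] = None
    neck_cm_questionnaire: Optional[float] = None
    waist_cm: Optional[float] = None
    snoring_quality: Optional[int] = None
    tiredness_freq: Optional[int] = None
    berlin_cat1_positive_items: int = 0
    berlin_cat2_positive_items: int = 0
    mwt_latency_min: Optional[float] = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.age_years > 0:
            raise ValidationError(f"age_years must be positive, got {self.age_years}")
        if not self.bmi_visit > 0:
            raise ValidationError(f"bmi_visit must be positive, got {self.bmi_visit}")
        if not self.neck_cm_visit > 0:
            raise ValidationError(
                f"neck_cm_visit must be positive, got {self.neck_cm_visit}"
            )
        for name in ("snoring_freq", "apnea_freq"):
            v = getattr(self, name)
            if not (BNSQ_MIN <= int(v) <= BNSQ_MAX):
                raise ValidationError(f"{name} must be in 1..5, got {v}")
            setattr(self, name, int(v))
        for name in ("snoring_quality", "tiredness_freq"):
            v = getattr(self, name)
            if v is not None:
                if not (BNSQ_MIN <= int(v) <= BNSQ_MAX):
                    raise ValidationError(f"{name} must be in 1..5, got {v}")
                setattr(self, name, int(v))
        items = [int(v) for v in self.ess_items]
        if len(items) != ESS_N_ITEMS:
            raise ValidationError(f"ess_items must have {ESS_N_ITEMS} entries")
        if any(not (0 <= v <= ESS_ITEM_MAX) for v in items):
            raise ValidationError(f"each ESS item must be in 0..{ESS_ITEM_MAX}")
        self.ess_items = tuple(items)
        if self.ahi < 0:
            raise ValidationError(f"ahi must be >= 0, got {self.ahi}")
        for name in ("berlin_cat1_positive_items", "berlin_cat2_positive_items"):
            if int(getattr(self, name)) < 0:
                raise ValidationError(f"{name} must be >= 0")
        self.hypertension = bool(self.hypertension)

    @property
    def is_male(self) -> bool:
        return self.sex == "male"


_OPTIONAL_FLOATS = (
    "bmi_questionnaire",
    "neck_cm_questionnaire",
    "waist_cm",
    "mwt_latency_min",
)
_OPTIONAL_INTS = ("snoring_quality", "tiredness_freq")

COHORT_COLUMNS = [
    "id",
    "sex",
    "age_years",
    "bmi_visit",
    "bmi_questionnaire",
    "neck_cm_visit",
    "neck_cm_questionnaire",
    "waist_cm",
    "snoring_freq",
    "snoring_quality",
    "apnea_freq",
    "tiredness_freq",
    "hypertension",
    *[f"ess{i}" for i in range(1, ESS_N_ITEMS + 1)],
    "berlin_cat1_positive_items",
    "berlin_cat2_positive_items",
    "ahi",
    "mwt_latency_min",
]


def record_to_row(r: RespondentRecord) -> dict:
    row = {}
    for f in fields(r):
        if f.name == "ess_items":
            for i, v in enumerate(r.ess_items, start=1):
                row[f"ess{i}"] = v
        elif f.name == "hypertension":
            row["hypertension"] = int(r.hypertension)
        else:
            row[f.name] = getattr(r, f.name)
    return row


def record_from_row(row: dict) -> RespondentRecord:
    def opt(name, cast):
        v = row.get(name)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return cast(v)

    return RespondentRecord(
        id=str(row["id"]),
        sex=str(row["sex"]),
        age_years=float(row["age_years"]),
        bmi_visit=float(row["bmi_visit"]),
        neck_cm_visit=float(row["neck_cm_visit"]),
        snoring_freq=int(row["snoring_freq"]),
        apnea_freq=int(row["apnea_freq"]),
        hypertension=bool(int(row["hypertension"])),
        ess_items=[int(row[f"ess{i}"]) for i in range(1, ESS_N_ITEMS + 1)],
        ahi=float(row["ahi"]),
        berlin_cat1_positive_items=int(row.get("berlin_cat1_positive_items", 0)),
        berlin_cat2_positive_items=int(row.get("berlin_cat2_positive_items", 0)),
        **{name: opt(name, float) for name in _OPTIONAL_FLOATS},
        **{name: opt(name, int) for name in _OPTIONAL_INTS},
    )


def cohort_to_frame(records: Sequence[RespondentRecord]) -> pd.DataFrame:
    df = pd.DataFrame([record_to_row(r) for r in records])
    return df[COHORT_COLUMNS]


def frame_to_cohort(df: pd.DataFrame) -> list[RespondentRecord]:
    return [record_from_row(row) for row in df.to_dict(orient="records")]


def write_cohort(records: Sequence[RespondentRecord], path, sep: str = ",") -> None:
    cohort_to_frame(records).to_csv(path, sep=sep, index=False, float_format="%.6g")


def read_cohort(path, sep: str = ",") -> list[RespondentRecord]:
    """Read a cohort file; raises ValidationError for out-of-range fields."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c in (
        "id", "sex", "age_years", "bmi_visit", "neck_cm_visit",
        "snoring_freq", "apnea_freq", "hypertension", "ahi",
        *[f"ess{i}" for i in range(1, ESS_N_ITEMS + 1)],
    )]
    if missing:
        raise ValidationError(f"cohort file missing required columns: {missing}")
    return frame_to_cohort(df)
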