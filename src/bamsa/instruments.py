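"""Screening-instrument scoring.

Implements the five-item BAMSA score together with the comparator
instruments it was evaluated against: STOP-BANG (original and updated
neck-circumference criteria), NoSAS, the Berlin questionnaire and the
Epworth Sleepiness Scale (ESS), plus the questionnaire→visit calibration
lines for self-reported BMI and neck circumference.

BAMSA assigns one point for each of: BMI > 30 kg/m², age > 50 years, male
sex, snoring at least one night per week, and witnessed breathing pauses at
least sometimes (any BNSQ response above "never").  Both anthropometric
thresholds are strict, so boundary values contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .config import DEFAULT_CONFIG, InstrumentConfig
from .exceptions import MissingDataError, ValidationError
from .records import RespondentRecord


@dataclass(frozen=True)
class InstrumentResult:
    """A named score value plus its binary classification at a cut-off."""

    instrument: str
    score: Union[int, float]
    cutoff: Union[int, float]
    positive: bool


@dataclass(frozen=True)
class BerlinResult:
    """Berlin questionnaire outcome: per-category flags and overall risk."""

    cat1_positive: bool
    cat2_positive: bool
    cat3_positive: bool
    high_risk: bool

    @property
    def n_positive_categories(self) -> int:
        return int(self.cat1_positive) + int(self.cat2_positive) + int(self.cat3_positive)


def _require(record: RespondentRecord, field: str):
    value = getattr(record, field)
    if value is None:
        raise MissingDataError(
            f"respondent {record.id!r}: field {field!r} is required but missing"
        )
    return value


def score_bamsa(
    r: RespondentRecord, config: InstrumentConfig = DEFAULT_CONFIG
) -> int:
    """BAMSA score, 0–5: BMI, Age, Male, Snoring, Apneas (one point each)."""
    bmi = _require(r, "bmi_visit")
    age = _require(r, "age_years")
    snoring = _require(r, "snoring_freq")
    apnea = _require(r, "apnea_freq")
    return (
        int(bmi > config.bamsa_bmi_over)
        + int(age > config.bamsa_age_over)
        + int(r.is_male)
        + int(snoring >= config.snoring_weekly_min_freq)
        + int(apnea >= config.apnea_min_freq)
    )


def score_stop_bang(
    r: RespondentRecord,
    nc_variant: str = "original",
    config: InstrumentConfig = DEFAULT_CONFIG,
) -> int:
    """Eight-item STOP-BANG score, 0–8.

    ``nc_variant='original'`` uses neck circumference > 40 cm for both
    sexes; ``'new'`` uses the updated sex-specific thresholds (defaults
    male > 43 cm, female > 41 cm, configurable).  The snoring, tiredness
    and observed-apnea yes/no items are derived from the BNSQ frequency
    items using the same mappings as BAMSA (see config).
    """
    if nc_variant not in ("original", "new"):
        raise ValidationError(f"unknown STOP-BANG variant {nc_variant!r}")
    neck = _require(r, "neck_cm_visit")
    tiredness = _require(r, "tiredness_freq")
    if nc_variant == "original":
        neck_item = neck > config.stopbang_neck_over_cm
    else:
        threshold = (
            config.stopbang_neck_over_cm_male
            if r.is_male
            else config.stopbang_neck_over_cm_female
        )
        neck_item = neck > threshold
    return (
        int(_require(r, "snoring_freq") >= config.snoring_weekly_min_freq)  # S
        + int(tiredness >= config.tiredness_min_freq)  # T
        + int(_require(r, "apnea_freq") >= config.apnea_min_freq)  # O
        + int(_require(r, "hypertension"))  # P
        + int(_require(r, "bmi_visit") > config.stopbang_bmi_over)  # B
        + int(_require(r, "age_years") > config.stopbang_age_over)  # A
        + int(neck_item)  # N
        + int(r.is_male)  # G
    )


def score_nosas(
    r: RespondentRecord, config: InstrumentConfig = DEFAULT_CONFIG
) -> int:
    """NoSAS score, 0–17 (neck > 40 cm: 4; BMI 25–<30: 3, ≥30: 5;
    snorer: 2; age > 55: 4; male: 2)."""
    neck = _require(r, "neck_cm_visit")
    bmi = _require(r, "bmi_visit")
    score = 0
    if neck > config.nosas_neck_over_cm:
        score += config.nosas_neck_points
    if bmi >= config.nosas_bmi_high_lower:
        score += config.nosas_bmi_high_points
    elif bmi >= config.nosas_bmi_mid_lower:
        score += config.nosas_bmi_mid_points
    if _require(r, "snoring_freq") >= config.snoring_weekly_min_freq:
        score += config.nosas_snorer_points
    if _require(r, "age_years") > config.nosas_age_over:
        score += config.nosas_age_points
    if r.is_male:
        score += config.nosas_male_points
    return score


def score_berlin(
    r: RespondentRecord, config: InstrumentConfig = DEFAULT_CONFIG
) -> BerlinResult:
    """Berlin questionnaire risk category.

    Categories 1 (snoring/apneas) and 2 (tiredness/drowsy driving) are
    positive with at least two positive items; category 3 is positive with
    hypertension or BMI > 30.  High risk requires at least two positive
    categories.  Category 1/2 items are accepted pre-tallied.
    """
    cat1 = r.berlin_cat1_positive_items >= config.berlin_items_per_category
    cat2 = r.berlin_cat2_positive_items >= config.berlin_items_per_category
    cat3 = bool(_require(r, "hypertension")) or (
        _require(r, "bmi_visit") > config.berlin_bmi_over
    )
    n_pos = int(cat1) + int(cat2) + int(cat3)
    return BerlinResult(
        cat1_positive=cat1,
        cat2_positive=cat2,
        cat3_positive=cat3,
        high_risk=n_pos >= config.berlin_high_risk_categories,
    )


def score_ess(r: RespondentRecord, config: InstrumentConfig = DEFAULT_CONFIG) -> int:
    """Epworth Sleepiness Scale total, 0–24 (sum of 8 items scored 0–3)."""
    items = _require(r, "ess_items")
    # range validation happens in RespondentRecord; re-check when called
    # with a duck-typed record
    if len(items) != 8 or any(not (0 <= int(v) <= 3) for v in items):
        raise ValidationError("ESS requires 8 items each in 0..3")
    return int(sum(int(v) for v in items))


#: Printed least-squares calibration lines mapping a questionnaire
#: self-report to the measured visit scale.
CALIBRATION_LINES = {
    "bmi": (2.36, 0.913),
    "neck": (18.47, 0.548),
}


def calibrate_questionnaire_measurement(x: float, measurement: str) -> float:
    """Predict the measured (visit) value from a questionnaire self-report.

    ``measurement`` is ``'bmi'`` (kg/m²) or ``'neck'`` (cm).
    """
    if measurement not in CALIBRATION_LINES:
        raise ValidationError(f"unknown measurement {measurement!r}")
    if not x > 0:
        raise ValidationError(f"measurement must be positive, got {x}")
    intercept, slope = CALIBRATION_LINES[measurement]
    return intercept + slope * x


def classify(
    instrument: str,
    score: Union[int, float],
    cutoff: Union[int, float],
) -> InstrumentResult:
    """Binary classification at a cut-off (positive ⇔ score ≥ cutoff)."""
    return InstrumentResult(
        instrument=instrument, score=score, cutoff=cutoff, positive=score >= cutoff
    )
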