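"""Tunable instrument thresholds.

All cut-offs that the instruments depend on live here so that the mapping
from the semi-quantitative BNSQ frequency items to the yes/no items of
STOP-BANG/NoSAS, and the sex-specific neck thresholds of the updated
STOP-BANG, can be changed without touching scoring code.  The config can be
round-tripped through a human-readable YAML file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml


@dataclass(frozen=True)
class InstrumentConfig:
    # BAMSA item thresholds (strict inequalities: boundary values score 0)
    bamsa_bmi_over: float = 30.0
    bamsa_age_over: float = 50.0

    # BNSQ frequency -> binary mappings.  Response 3 = "on 1-2 nights per
    # week", so snoring at least one night per week <=> freq >= 3; witnessed
    # apneas "at least sometimes" <=> any response above "never" (freq >= 2).
    snoring_weekly_min_freq: int = 3
    apnea_min_freq: int = 2
    tiredness_min_freq: int = 3

    # STOP-BANG
    stopbang_bmi_over: float = 35.0
    stopbang_age_over: float = 50.0
    stopbang_neck_over_cm: float = 40.0  # original criteria, both sexes
    stopbang_neck_over_cm_male: float = 43.0  # updated sex-specific criteria
    stopbang_neck_over_cm_female: float = 41.0

    # NoSAS published weights
    nosas_neck_over_cm: float = 40.0
    nosas_neck_points: int = 4
    nosas_bmi_mid_lower: float = 25.0
    nosas_bmi_mid_points: int = 3
    nosas_bmi_high_lower: float = 30.0
    nosas_bmi_high_points: int = 5
    nosas_snorer_points: int = 2
    nosas_age_over: float = 55.0
    nosas_age_points: int = 4
    nosas_male_points: int = 2
    nosas_high_risk_cutoff: int = 8

    # Berlin
    berlin_items_per_category: int = 2  # positive items needed in cat 1/2
    berlin_bmi_over: float = 30.0
    berlin_high_risk_categories: int = 2

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "InstrumentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


DEFAULT_CONFIG = InstrumentConfig()
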