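"""Synthetic male professional-driver cohorts.

The study population this generator emulates is a cohort of 160 male truck
drivers with questionnaire data and cardiorespiratory polygraphy.  The
generative model is:

* anthropometrics — age ~ truncated normal(42.0, 9.3) on [20, 58] years;
  BMI ~ truncated normal(28.3, 5.1) on [19, 47] kg/m²; neck circumference
  built from BMI with correlation 0.6 around mean 41.2 cm (SD 3.1); waist
  linearly linked to BMI (mean 101.4 cm, SD 15.2, r = 0.85);
* sleep-apnea severity — a latent liability, a linear combination of
  standardized BMI, age and neck plus Gaussian noise, drives log-AHI.
  AHI is a zero-heavy lognormal: with probability ``p_low`` the subject is
  a floor case (AHI uniform on [0, 2]); otherwise AHI = exp(mu + scale*W)
  with W the standardized liability, capped at 120 events/h.  The triple
  (p_low, mu, scale) is solved numerically so that the cohort reproduces
  the three exceedance probabilities P(AHI>=5) = 0.4375, P(AHI>=15) =
  0.175 and P(AHI>=30) = 0.075;
* questionnaire items — snoring and witnessed-apnea BNSQ frequencies are
  drawn from probability tables conditional on the severity class
  (none/mild/moderate/severe), chosen to match the marginal item
  prevalences (habitual snoring 43.75%, never-snorers 16.9%, apneas at
  least sometimes 53.75%) and the printed snoring-by-AHI joint facts;
  the severe-with-no-snoring corner has positive mass;
* Epworth items — a per-person propensity p ~ Beta(4.83, 8.50) with items
  Binomial(3, p), independent of AHI (total mean ≈ 8.7, SD ≈ 3.8), so the
  ESS discriminates sleep apnea no better than chance;
* hypertension ~ Bernoulli(0.169), independent;
* MWT mean latency ~ normal with class-dependent mean (SD 10 min, clipped
  to [0, 40]), calibrated so P(MWT < 19.4 min) ≈ 0.205 and
  P(AHI>=5 & MWT < 19.4) ≈ 0.122; about 2.5% of MWT values are missing.

All randomness flows from a single seed; per-variable sub-streams are
spawned deterministically so that changing one structural coefficient
leaves the random draws of every other variable unchanged (common random
numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import truncnorm

from .exceptions import ValidationError
from .records import RespondentRecord

#: severity classes: AHI < 5 (none), 5–15 (mild), 15–30 (moderate), >= 30
SEVERITY_EDGES = (5.0, 15.0, 30.0)
SEVERITY_NAMES = ("none", "mild", "moderate", "severe")

# Internal entropy for the calibration reference sample.  This is part of
# the model definition (it fixes the quantile grid the exceedance solve is
# performed on), not a per-run seed.
_CALIBRATION_ENTROPY = 771_003_151
_N_REFERENCE = 200_000


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of the synthetic cohort."""

    n: int = 160
    seed: int = 0

    # anthropometrics
    age_mean: float = 42.0
    age_sd: float = 9.3
    age_min: float = 20.0
    age_max: float = 58.0
    bmi_mean: float = 28.3
    bmi_sd: float = 5.1
    bmi_min: float = 19.0
    bmi_max: float = 47.0
    neck_mean: float = 41.2
    neck_sd: float = 3.1
    neck_min: float = 35.0
    neck_max: float = 52.0
    neck_bmi_corr: float = 0.6
    waist_mean: float = 101.4
    waist_sd: float = 15.2
    waist_bmi_corr: float = 0.85

    # log-AHI liability: coefficients on standardized BMI, age, neck
    beta_bmi: float = 0.55
    beta_age: float = 0.25
    beta_neck: float = 0.30
    log_ahi_noise_sd: float = 1.13
    ahi_thresholds: Tuple[float, float, float] = SEVERITY_EDGES
    ahi_exceedance: Tuple[float, float, float] = (0.4375, 0.175, 0.075)
    ahi_cap: float = 120.0
    low_ahi_max: float = 2.0

    # filled in by calibration
    p_low: Optional[float] = None
    log_ahi_mu: Optional[float] = None
    log_ahi_scale: Optional[float] = None
    liability_mean: Optional[float] = None
    liability_sd: Optional[float] = None

    # BNSQ item tables, rows = severity class, columns = frequency 1..5
    snoring_table: Tuple[Tuple[float, ...], ...] = (
        (0.200, 0.374, 0.050, 0.040, 0.336),  # none
        (0.167, 0.316, 0.035, 0.032, 0.450),  # mild
        (0.070, 0.130, 0.045, 0.035, 0.720),  # moderate
        (0.073, 0.077, 0.038, 0.032, 0.780),  # severe
    )
    apnea_table: Tuple[Tuple[float, ...], ...] = (
        (0.635, 0.160, 0.068, 0.065, 0.072),  # none
        (0.320, 0.150, 0.090, 0.160, 0.280),  # mild
        (0.150, 0.070, 0.050, 0.180, 0.550),  # moderate
        (0.080, 0.025, 0.015, 0.130, 0.750),  # severe
    )

    # ESS: per-person propensity Beta(a, b), 8 items Binomial(3, p)
    ess_beta_a: float = 4.83
    ess_beta_b: float = 8.50

    # daytime tiredness frequency 1..5, independent marginal
    tiredness_probs: Tuple[float, ...] = (0.08, 0.09, 0.624, 0.13, 0.076)

    hypertension_p: float = 0.169

    # MWT latency: class-dependent means, common SD, ceiling at 40 min
    mwt_class_means: Tuple[float, float, float, float] = (29.5, 26.5, 24.5, 23.0)
    mwt_sd: float = 10.0
    mwt_max: float = 40.0
    mwt_missing_p: float = 0.025

    # questionnaire self-report noise around the inverted calibration lines
    bmi_questionnaire_noise_sd: float = 0.8
    neck_questionnaire_noise_sd: float = 2.5

    def validate(self) -> None:
        for name in ("snoring_table", "apnea_table"):
            table = np.asarray(getattr(self, name), dtype=float)
            if table.shape != (4, 5):
                raise ValidationError(f"{name} must be 4 classes x 5 frequencies")
            if (table < 0).any() or (table > 1).any():
                raise ValidationError(f"{name} entries must be probabilities")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-6):
                raise ValidationError(f"{name} rows must sum to 1")
        probs = np.asarray(self.tiredness_probs, dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValidationError("tiredness_probs must be a distribution")
        if not (0.0 <= self.hypertension_p <= 1.0):
            raise ValidationError("hypertension_p must be in [0, 1]")

    @property
    def is_calibrated(self) -> bool:
        return None not in (
            self.p_low, self.log_ahi_mu, self.log_ahi_scale,
            self.liability_mean, self.liability_sd,
        )


# ---------------------------------------------------------------------------
# liability machinery (shared by calibration and generation)

def _trunc(mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm(a, b, loc=mean, scale=sd)


def _covariate_z_moments(p: CohortParams):
    """Analytic mean/SD of the truncated age and BMI distributions."""
    age = _trunc(p.age_mean, p.age_sd, p.age_min, p.age_max)
    bmi = _trunc(p.bmi_mean, p.bmi_sd, p.bmi_min, p.bmi_max)
    return age.stats(moments="mv"), bmi.stats(moments="mv")


def _draw_covariates(p: CohortParams, rngs: dict, n: int):
    age = _trunc(p.age_mean, p.age_sd, p.age_min, p.age_max).rvs(
        n, random_state=rngs["age"]
    )
    bmi = _trunc(p.bmi_mean, p.bmi_sd, p.bmi_min, p.bmi_max).rvs(
        n, random_state=rngs["bmi"]
    )
    (_age_m, _age_v), (bmi_m, bmi_v) = _covariate_z_moments(p)
    z_bmi = (bmi - bmi_m) / np.sqrt(bmi_v)
    neck = p.neck_mean + p.neck_sd * (
        p.neck_bmi_corr * z_bmi
        + np.sqrt(max(0.0, 1.0 - p.neck_bmi_corr**2)) * rngs["neck"].standard_normal(n)
    )
    neck = np.clip(neck, p.neck_min, p.neck_max)
    slope = p.waist_bmi_corr * p.waist_sd / p.bmi_sd
    resid = p.waist_sd * np.sqrt(max(0.0, 1.0 - p.waist_bmi_corr**2))
    waist = p.waist_mean + slope * (bmi - p.bmi_mean) + resid * rngs[
        "waist"
    ].standard_normal(n)
    waist = np.clip(waist, 60.0, None)
    return age, bmi, neck, waist


def _raw_liability(p: CohortParams, age, bmi, neck, eps):
    (age_m, age_v), (bmi_m, bmi_v) = _covariate_z_moments(p)
    z_age = (age - age_m) / np.sqrt(age_v)
    z_bmi = (bmi - bmi_m) / np.sqrt(bmi_v)
    z_neck = (neck - p.neck_mean) / p.neck_sd
    return (
        p.beta_bmi * z_bmi
        + p.beta_age * z_age
        + p.beta_neck * z_neck
        + p.log_ahi_noise_sd * eps
    )


_STREAMS = (
    "age", "bmi", "neck", "waist", "liability_noise", "low_mass", "low_ahi",
    "snoring", "quality", "apnea", "tiredness", "hypertension", "ess",
    "mwt", "mwt_missing", "berlin1", "berlin2", "questionnaire",
)


def _spawn_rngs(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _reference_liability(p: CohortParams, n_ref: int = _N_REFERENCE) -> np.ndarray:
    ss = np.random.SeedSequence(_CALIBRATION_ENTROPY)
    rngs = {
        name: np.random.default_rng(c)
        for name, c in zip(_STREAMS, ss.spawn(len(_STREAMS)))
    }
    age, bmi, neck, _ = _draw_covariates(p, rngs, n_ref)
    eps = rngs["liability_noise"].standard_normal(n_ref)
    return _raw_liability(p, age, bmi, neck, eps)


def calibrate_params(p: CohortParams, n_ref: int = _N_REFERENCE) -> CohortParams:
    """Solve (p_low, mu, scale) so that the AHI exceedance probabilities
    hit their targets on a fixed reference sample of the liability.

    The reference sample uses the same code path as the generator, so the
    solve absorbs every non-normality introduced by truncation/clipping.
    """
    p.validate()
    raw = _reference_liability(p, n_ref)
    mean, sd = float(raw.mean()), float(raw.std())
    w_sorted = np.sort((raw - mean) / sd)
    # smooth piecewise-linear survival function of the standardized liability
    surv_y = 1.0 - (np.arange(1, n_ref + 1) - 0.5) / n_ref

    log_thr = np.log(np.asarray(p.ahi_thresholds, dtype=float))
    targets = np.asarray(p.ahi_exceedance, dtype=float)

    def survival(t):
        return np.interp(t, w_sorted, surv_y, left=1.0, right=0.0)

    def residuals(x):
        p_low, mu, scale = x
        return (1.0 - p_low) * survival((log_thr - mu) / scale) - targets

    sol = least_squares(
        residuals,
        x0=np.array([0.12, 1.60, 1.31]),
        bounds=([0.0, -2.0, 0.2], [0.5, 5.0, 4.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    p_low, mu, scale = sol.x
    return replace(
        p,
        p_low=float(p_low),
        log_ahi_mu=float(mu),
        log_ahi_scale=float(scale),
        liability_mean=mean,
        liability_sd=sd,
    )


_DEFAULT_CACHE: dict = {}


def calibrate_defaults(n: int = 160, seed: int = 0) -> CohortParams:
    """Packaged default parameter set, calibrated to the study marginals."""
    if "params" not in _DEFAULT_CACHE:
        _DEFAULT_CACHE["params"] = calibrate_params(CohortParams())
    return replace(_DEFAULT_CACHE["params"], n=n, seed=seed)


# ---------------------------------------------------------------------------
# generation

def _sample_rows(table: np.ndarray, classes: np.ndarray, rng) -> np.ndarray:
    """Draw one categorical value (1..k) per subject from its class row."""
    cum = np.cumsum(table, axis=1)
    u = rng.random(classes.size)
    return 1 + (u[:, None] > cum[classes]).sum(axis=1)


def severity_class(ahi: np.ndarray, edges=SEVERITY_EDGES) -> np.ndarray:
    return np.digitize(ahi, edges)


def generate_cohort(p: CohortParams) -> List[RespondentRecord]:
    """Generate a cohort of respondent records; deterministic given seed."""
    if not p.is_calibrated:
        raise ValidationError(
            "CohortParams not calibrated: use calibrate_defaults() or calibrate_params()"
        )
    p.validate()
    n = p.n
    rngs = _spawn_rngs(p.seed)

    age, bmi, neck, waist = _draw_covariates(p, rngs, n)
    eps = rngs["liability_noise"].standard_normal(n)
    w = (_raw_liability(p, age, bmi, neck, eps) - p.liability_mean) / p.liability_sd
    ahi = np.exp(p.log_ahi_mu + p.log_ahi_scale * w)
    ahi = np.minimum(ahi, p.ahi_cap)
    low = rngs["low_mass"].random(n) < p.p_low
    ahi[low] = rngs["low_ahi"].uniform(0.0, p.low_ahi_max, low.sum())

    classes = severity_class(ahi)
    snoring = _sample_rows(np.asarray(p.snoring_table), classes, rngs["snoring"])
    apnea = _sample_rows(np.asarray(p.apnea_table), classes, rngs["apnea"])

    # snoring quality: deterministic "never" for non-snorers, otherwise a
    # loudness distribution that shifts up with snoring frequency
    quality = np.ones(n, dtype=int)
    qrng = rngs["quality"]
    for freq, choices, probs in (
        (2, [2, 3], [0.7, 0.3]),
        (3, [2, 3, 4, 5], [0.2, 0.35, 0.3, 0.15]),
        (4, [2, 3, 4, 5], [0.2, 0.35, 0.3, 0.15]),
        (5, [3, 4, 5], [0.15, 0.35, 0.5]),
    ):
        mask = snoring == freq
        quality[mask] = qrng.choice(choices, size=mask.sum(), p=probs)

    tiredness = 1 + (
        rngs["tiredness"].random(n)[:, None]
        > np.cumsum(p.tiredness_probs)
    ).sum(axis=1)
    hypertension = rngs["hypertension"].random(n) < p.hypertension_p

    propensity = rngs["ess"].beta(p.ess_beta_a, p.ess_beta_b, n)
    ess_items = rngs["ess"].binomial(3, propensity[:, None], size=(n, 8))

    mwt_mean = np.asarray(p.mwt_class_means)[classes]
    mwt = np.clip(
        rngs["mwt"].normal(mwt_mean, p.mwt_sd), 0.0, p.mwt_max
    )
    mwt_missing = rngs["mwt_missing"].random(n) < p.mwt_missing_p

    p_cat1 = np.clip(
        0.04 * snoring + 0.08 * apnea + 0.10 * (quality >= 4), 0.0, 0.95
    )
    berlin1 = rngs["berlin1"].binomial(4, p_cat1)
    p_cat2 = np.clip(0.10 + 0.15 * (tiredness - 1), 0.0, 0.95)
    berlin2 = rngs["berlin2"].binomial(3, p_cat2)

    qrng2 = rngs["questionnaire"]
    bmi_q = (bmi - 2.36) / 0.913 + qrng2.normal(0.0, p.bmi_questionnaire_noise_sd, n)
    neck_q = (neck - 18.47) / 0.548 + qrng2.normal(
        0.0, p.neck_questionnaire_noise_sd, n
    )

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(
            RespondentRecord(
                id=f"D{i + 1:0{width}d}",
                sex="male",
                age_years=float(age[i]),
                bmi_visit=float(bmi[i]),
                bmi_questionnaire=float(max(bmi_q[i], 12.0)),
                neck_cm_visit=float(neck[i]),
                neck_cm_questionnaire=float(max(neck_q[i], 25.0)),
                waist_cm=float(waist[i]),
                snoring_freq=int(snoring[i]),
                snoring_quality=int(quality[i]),
                apnea_freq=int(apnea[i]),
                tiredness_freq=int(tiredness[i]),
                hypertension=bool(hypertension[i]),
                ess_items=[int(v) for v in ess_items[i]],
                berlin_cat1_positive_items=int(berlin1[i]),
                berlin_cat2_positive_items=int(berlin2[i]),
                ahi=float(ahi[i]),
                mwt_latency_min=None if mwt_missing[i] else float(mwt[i]),
            )
        )
    return records
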