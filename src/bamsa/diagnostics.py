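"""Diagnostic-accuracy statistics.

Everything a 2x2 screening-test table yields — sensitivity, specificity,
predictive values with exact Clopper–Pearson intervals, likelihood ratios,
the diagnostic odds ratio (LR+/LR−) and the dichotomized ROC area
(sens+spec)/2 — plus rank-based ROC/AUC for graded scores and the DeLong
test for paired AUC comparison, with a stratified-bootstrap cross-check.

Positivity convention throughout: a subject is test-positive when
score >= cutoff.  Ties in the AUC contribute 1/2 (Mann–Whitney convention).
Statistics with a zero denominator are reported as ``None`` (undefined),
never as infinity; a test with sensitivity 1 has LR− = 0 and therefore an
undefined odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

from .exceptions import SingleClassError, ValidationError


# ---------------------------------------------------------------------------
# 2x2 tables

@dataclass(frozen=True)
class ConfusionTable:
    """Integer TP/FP/FN/TN counts against a chosen reference definition."""

    tp: int
    fp: int
    fn: int
    tn: int
    reference_label: str = ""
    test_label: str = ""

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))
        if self.n == 0:
            raise ValidationError("confusion table must contain at least one subject")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        """Reference-positive count."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @classmethod
    def from_predictions(
        cls, predicted, outcome, reference_label: str = "", test_label: str = ""
    ) -> "ConfusionTable":
        predicted = np.asarray(predicted, dtype=bool)
        outcome = np.asarray(outcome, dtype=bool)
        if predicted.shape != outcome.shape:
            raise ValidationError("predicted and outcome must have equal length")
        return cls(
            tp=int(np.sum(predicted & outcome)),
            fp=int(np.sum(predicted & ~outcome)),
            fn=int(np.sum(~predicted & outcome)),
            tn=int(np.sum(~predicted & ~outcome)),
            reference_label=reference_label,
            test_label=test_label,
        )


@dataclass(frozen=True)
class Proportion:
    """A binomial proportion with a two-sided exact 95% interval."""

    value: float
    ci_low: float
    ci_high: float
    count: int
    nobs: int


@dataclass(frozen=True)
class AccuracySummary:
    """The eight accuracy statistics of a dichotomized screening test."""

    sens: Optional[Proportion]
    spec: Optional[Proportion]
    ppv: Optional[Proportion]
    npv: Optional[Proportion]
    lr_pos: Optional[float]
    lr_neg: Optional[float]
    odds_ratio: Optional[float]
    roc_area_dichotomous: Optional[float]
    table: ConfusionTable = field(repr=False, default=None)


def _proportion(count: int, nobs: int, alpha: float) -> Optional[Proportion]:
    if nobs == 0:
        return None
    low, high = proportion_confint(count, nobs, alpha=alpha, method="beta")
    return Proportion(
        value=count / nobs,
        ci_low=float(low),
        ci_high=float(high),
        count=count,
        nobs=nobs,
    )


def accuracy_metrics(t: ConfusionTable, alpha: float = 0.05) -> AccuracySummary:
    """All accuracy statistics of a 2x2 table.

    The odds ratio is LR+/LR− which, whenever all four cells are positive,
    equals the cross-product (tp*tn)/(fp*fn) exactly.  Any statistic whose
    denominator is zero (or whose LR− is zero, for the OR) is ``None``.
    """
    sens = _proportion(t.tp, t.n_pos, alpha)
    spec = _proportion(t.tn, t.n_neg, alpha)
    ppv = _proportion(t.tp, t.tp + t.fp, alpha)
    npv = _proportion(t.tn, t.tn + t.fn, alpha)

    lr_pos = lr_neg = odds_ratio = roc = None
    if sens is not None and spec is not None:
        if spec.value < 1.0:
            lr_pos = sens.value / (1.0 - spec.value)
        if spec.value > 0.0:
            lr_neg = (1.0 - sens.value) / spec.value
        if lr_pos is not None and lr_neg is not None and lr_neg > 0.0:
            # identical to lr_pos/lr_neg but exact in the cells (keeps
            # decimal ties like 528/128 = 4.125 exact for formatting)
            odds_ratio = (t.tp * t.tn) / (t.fp * t.fn)
        roc = (sens.value + spec.value) / 2.0
    return AccuracySummary(
        sens=sens,
        spec=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        odds_ratio=odds_ratio,
        roc_area_dichotomous=roc,
        table=t,
    )


# ---------------------------------------------------------------------------
# ROC / AUC

def _check_two_class(scores, outcome) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if scores.shape != outcome.shape or scores.ndim != 1:
        raise ValidationError("scores and outcome must be 1-D of equal length")
    if outcome.all() or not outcome.any():
        raise SingleClassError("outcome must contain both classes")
    return scores, outcome


@dataclass(frozen=True)
class RocCurve:
    """ROC points (1−specificity, sensitivity) over all distinct cut-offs."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # positivity: score >= threshold

    @property
    def points(self):
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def roc_curve(scores: Sequence[float], outcome: Sequence[bool]) -> RocCurve:
    """ROC curve with positivity defined as score >= cut-off.

    Points are anchored at (0,0) (cut-off above the maximum score) and
    (1,1) (cut-off at the minimum score) and are monotone non-decreasing
    in both coordinates.
    """
    scores, outcome = _check_two_class(scores, outcome)
    cutoffs = np.unique(scores)[::-1]  # descending
    pos = scores[outcome]
    neg = scores[~outcome]
    tpr = [0.0]
    fpr = [0.0]
    for c in cutoffs:
        tpr.append(float(np.mean(pos >= c)))
        fpr.append(float(np.mean(neg >= c)))
    thresholds = np.concatenate(([np.inf], cutoffs))
    return RocCurve(fpr=np.array(fpr), tpr=np.array(tpr), thresholds=thresholds)


def auc(scores: Sequence[float], outcome: Sequence[bool]) -> float:
    """Tie-corrected ROC area: P(S+ > S−) + 0.5·P(S+ = S−).

    Computed from midranks, which coincides with the trapezoidal area under
    :func:`roc_curve`.
    """
    scores, outcome = _check_two_class(scores, outcome)
    m = int(outcome.sum())
    n = outcome.size - m
    ranks = rankdata(scores)
    return float((ranks[outcome].sum() - m * (m + 1) / 2.0) / (m * n))


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison

def _midrank(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")


def _delong_components(scores: np.ndarray, outcome: np.ndarray):
    """AUC and its positive/negative structural components (V10, V01)."""
    pos = scores[outcome]
    neg = scores[~outcome]
    m, n = pos.size, neg.size
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    aucval = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # per positive subject
    v01 = 1.0 - (tz[m:] - ty) / m    # per negative subject
    return aucval, v10, v01


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcome: Sequence[bool],
) -> DelongResult:
    """DeLong test for H0: AUC_a = AUC_b on paired scores.

    Uses the asymptotic normal distribution of the AUC difference with the
    DeLong covariance of the paired empirical AUCs.  Symmetric in (a, b):
    swapping the classifiers negates z and leaves p unchanged.  Identical
    score vectors give z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValidationError("paired score vectors must have equal length")
    _, outcome = _check_two_class(scores_a, outcome)

    auc_a, v10_a, v01_a = _delong_components(scores_a, outcome)
    auc_b, v10_b, v01_b = _delong_components(scores_b, outcome)
    m, n = v10_a.size, v01_a.size

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b

    if var_diff <= np.finfo(float).eps:
        z = 0.0 if diff == 0.0 else np.sign(diff) * np.inf
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * norm.sf(abs(z)))
    return DelongResult(
        auc_a=float(auc_a), auc_b=float(auc_b),
        var_diff=float(var_diff), z=float(z), p_value=float(p),
    )


@dataclass(frozen=True)
class BootstrapCompareResult:
    auc_a: float
    auc_b: float
    se_diff: float
    z: float
    p_value: float
    n_boot: int


def bootstrap_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcome: Sequence[bool],
    n_boot: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> BootstrapCompareResult:
    """Stratified-bootstrap alternative to :func:`delong_compare`.

    Cases and controls are resampled separately; the p-value uses the
    normal approximation with the bootstrap standard error of the paired
    AUC difference.  Serves as an independent cross-check of the DeLong
    variance estimate.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    _, outcome = _check_two_class(scores_a, outcome)
    rng = rng or np.random.default_rng()

    pos_idx = np.flatnonzero(outcome)
    neg_idx = np.flatnonzero(~outcome)
    auc_a = auc(scores_a, outcome)
    auc_b = auc(scores_b, outcome)

    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos_idx, pos_idx.size), rng.choice(neg_idx, neg_idx.size)]
        )
        out = np.concatenate(
            [np.ones(pos_idx.size, bool), np.zeros(neg_idx.size, bool)]
        )
        diffs[b] = auc(scores_a[idx], out) - auc(scores_b[idx], out)

    se = float(np.std(diffs, ddof=1))
    diff = auc_a - auc_b
    if se == 0.0:
        z, p = (0.0, 1.0) if diff == 0.0 else (np.sign(diff) * np.inf, 0.0)
    else:
        z = diff / se
        p = float(2.0 * norm.sf(abs(z)))
    return BootstrapCompareResult(
        auc_a=auc_a, auc_b=auc_b, se_diff=se, z=float(z), p_value=p, n_boot=n_boot
    )
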