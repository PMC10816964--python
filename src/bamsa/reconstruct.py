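"""Recover integer 2x2 tables from rounded published statistics.

A published accuracy row prints sensitivity and specificity rounded to a
fixed number of decimals.  Given the cohort size, the reference-positive
count and those two rounded percentages, the underlying integer table is
usually determined uniquely: tp must satisfy
round(100*tp/n_pos) == printed sensitivity, and tn likewise.  This module
performs that exhaustive search, refuses to guess when the printed values
are ambiguous, and verifies reconstructed tables against every derived
statistic of a printed row.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Union

from .diagnostics import ConfusionTable, accuracy_metrics
from .exceptions import AmbiguousReconstructionError, ReconstructionError, ValidationError
from .rounding import decimals_of, round_half_away

Printed = Union[str, float]


def _parse_printed(value: Printed, decimals: Optional[int]) -> tuple[float, int]:
    """Printed percentage -> (value, decimals). Strings carry their own
    precision ('97' means 0 decimals, '85.7' means 1)."""
    if isinstance(value, str):
        return float(value.strip().rstrip("%")), decimals_of(value)
    if decimals is None:
        raise ValidationError("decimals must be given when the printed value is numeric")
    return float(value), int(decimals)


def _solve_count(total: int, printed_pct: float, decimals: int, what: str) -> int:
    """Find the unique count k in 0..total with round(100*k/total) == printed."""
    if total <= 0:
        raise ValidationError(f"{what}: denominator must be positive")
    matches = [
        k
        for k in range(total + 1)
        if abs(round_half_away(100.0 * k / total, decimals) - printed_pct) < 1e-9
    ]
    if not matches:
        raise ReconstructionError(
            f"{what}: no count in 0..{total} rounds to {printed_pct} "
            f"at {decimals} decimal(s)"
        )
    if len(matches) > 1:
        raise AmbiguousReconstructionError(
            f"{what}: counts {matches} all round to {printed_pct} "
            f"at {decimals} decimal(s)",
            candidates=matches,
        )
    return matches[0]


def reconstruct_table(
    n: int,
    n_pos: int,
    sens_printed: Printed,
    spec_printed: Printed,
    decimals: Optional[int] = 1,
    reference_label: str = "",
    test_label: str = "",
) -> ConfusionTable:
    """Reconstruct the integer 2x2 table behind a printed accuracy row.

    ``sens_printed``/``spec_printed`` may be strings as printed (in which
    case the number of decimals is read off the string) or floats rounded
    to ``decimals`` places.  Raises :class:`ReconstructionError` when no
    integer table is consistent and :class:`AmbiguousReconstructionError`
    when more than one is.
    """
    if not (0 < n_pos < n):
        raise ValidationError(f"need 0 < n_pos < n, got n_pos={n_pos}, n={n}")
    sens_val, sens_dec = _parse_printed(sens_printed, decimals)
    spec_val, spec_dec = _parse_printed(spec_printed, decimals)
    for name, v in (("sensitivity", sens_val), ("specificity", spec_val)):
        if not (0.0 <= v <= 100.0):
            raise ValidationError(f"printed {name} must be in [0, 100], got {v}")
    n_neg = n - n_pos
    tp = _solve_count(n_pos, sens_val, sens_dec, "sensitivity")
    tn = _solve_count(n_neg, spec_val, spec_dec, "specificity")
    return ConfusionTable(
        tp=tp,
        fp=n_neg - tn,
        fn=n_pos - tp,
        tn=tn,
        reference_label=reference_label,
        test_label=test_label,
    )


# ---------------------------------------------------------------------------
# Verification against printed rows

@dataclass(frozen=True)
class PublishedRow:
    """One printed accuracy-table row, cells kept as printed strings.

    Empty strings mean the cell was not printed (e.g. the blank odds-ratio
    cell of a row with sensitivity 100%, whose LR− is 0).
    """

    table: str
    endpoint: str
    instrument: str
    cutoff: Optional[float]
    label: str
    n: int
    n_pos: int
    sens: str
    spec: str
    ppv: str = ""
    npv: str = ""
    lr_pos: str = ""
    lr_neg: str = ""
    odds_ratio: str = ""
    roc: str = ""


@dataclass(frozen=True)
class CellCheck:
    statistic: str
    printed: str
    computed: Optional[float]
    computed_rounded: Optional[float]
    match: bool


@dataclass(frozen=True)
class RowVerification:
    row: PublishedRow
    table: Optional[ConfusionTable]
    checks: List[CellCheck]
    error: Optional[str] = None

    @property
    def all_match(self) -> bool:
        return self.error is None and all(c.match for c in self.checks)

    @property
    def mismatches(self) -> List[CellCheck]:
        return [c for c in self.checks if not c.match]


def _computed_statistics(t: ConfusionTable) -> dict:
    s = accuracy_metrics(t)
    pct = lambda p: None if p is None else 100.0 * p.value  # noqa: E731
    return {
        "sens": pct(s.sens),
        "spec": pct(s.spec),
        "ppv": pct(s.ppv),
        "npv": pct(s.npv),
        "lr_pos": s.lr_pos,
        "lr_neg": s.lr_neg,
        "odds_ratio": s.odds_ratio,
        "roc": s.roc_area_dichotomous,
    }


def verify_row(t: ConfusionTable, row: PublishedRow) -> RowVerification:
    """Compare every printed cell of ``row`` with the statistic recomputed
    from ``t``, after rounding to the precision of the printed cell."""
    computed = _computed_statistics(t)
    checks: List[CellCheck] = []
    for stat, printed in (
        ("sens", row.sens), ("spec", row.spec), ("ppv", row.ppv), ("npv", row.npv),
        ("lr_pos", row.lr_pos), ("lr_neg", row.lr_neg),
        ("odds_ratio", row.odds_ratio), ("roc", row.roc),
    ):
        printed = (printed or "").strip()
        value = computed[stat]
        if printed == "":
            continue  # statistic not reported for this row
        if printed == "undef":
            # a deliberately blank published cell: the statistic has a zero
            # denominator (e.g. odds ratio of a test with sensitivity 100%)
            checks.append(CellCheck(stat, printed, value, None, value is None))
            continue
        target = float(printed.rstrip("%"))
        dec = decimals_of(printed)
        rounded = None if value is None else round_half_away(value, dec)
        match = rounded is not None and abs(rounded - target) < 1e-9
        checks.append(CellCheck(stat, printed, value, rounded, match))
    return RowVerification(row=row, table=t, checks=checks)


def reconstruct_and_verify(row: PublishedRow) -> RowVerification:
    try:
        t = reconstruct_table(
            n=row.n,
            n_pos=row.n_pos,
            sens_printed=row.sens,
            spec_printed=row.spec,
            reference_label=row.endpoint,
            test_label=row.label,
        )
    except ReconstructionError as exc:
        return RowVerification(row=row, table=None, checks=[], error=str(exc))
    return verify_row(t, row)


def load_published_rows() -> List[PublishedRow]:
    """Published accuracy rows packaged with the library (tab-delimited)."""
    text = (
        resources.files("bamsa.data")
        .joinpath("published_accuracy_rows.tsv")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        cells = dict(zip(header, ln.split("\t")))
        rows.append(
            PublishedRow(
                table=cells["table"],
                endpoint=cells["endpoint"],
                instrument=cells["instrument"],
                cutoff=float(cells["cutoff"]) if cells.get("cutoff") else None,
                label=cells["label"],
                n=int(cells["n"]),
                n_pos=int(cells["n_pos"]),
                sens=cells["sens"],
                spec=cells["spec"],
                ppv=cells.get("ppv", ""),
                npv=cells.get("npv", ""),
                lr_pos=cells.get("lr_pos", ""),
                lr_neg=cells.get("lr_neg", ""),
                odds_ratio=cells.get("odds_ratio", ""),
                roc=cells.get("roc", ""),
            )
        )
    return rows
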