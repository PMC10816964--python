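"""End-to-end evaluation of screening instruments on a cohort.

Given respondent records, a set of instrument/cut-off requests and a
reference endpoint (an AHI threshold, optionally combined with an abnormal
MWT), this module produces one accuracy row per instrument/cut-off, the
overall multi-cutoff AUC of each instrument, and pairwise DeLong
comparisons; and it re-derives every published accuracy row from its
reconstructed 2x2 table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import DEFAULT_CONFIG, InstrumentConfig
from .diagnostics import (
    AccuracySummary,
    ConfusionTable,
    DelongResult,
    accuracy_metrics,
    auc,
    delong_compare,
)
from .exceptions import MissingDataError, SingleClassError, ValidationError
from .instruments import (
    score_bamsa,
    score_berlin,
    score_ess,
    score_nosas,
    score_stop_bang,
)
from .records import RespondentRecord
from .reconstruct import (
    PublishedRow,
    RowVerification,
    load_published_rows,
    reconstruct_and_verify,
)
from .rounding import fmt_fixed, fmt_signif

# ---------------------------------------------------------------------------
# endpoints

MWT_ABNORMAL_MIN = 19.4

ENDPOINTS = ("AHI>=5", "AHI>=15", "AHI>=30", "AHI>=5&MWT<19.4")


def endpoint_outcome(
    records: Sequence[RespondentRecord], endpoint: str
) -> Tuple[List[RespondentRecord], np.ndarray]:
    """Resolve an endpoint to (complete-case records, boolean outcome).

    The MWT-combined endpoint keeps only subjects with an MWT result
    (complete-case, as in the source analysis); a plain AHI endpoint uses
    everyone.
    """
    key = endpoint.replace(" ", "")
    if key not in ENDPOINTS:
        raise ValidationError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    if key == "AHI>=5&MWT<19.4":
        if all(r.mwt_latency_min is None for r in records):
            raise MissingDataError(
                "endpoint requires column 'mwt_latency_min' but no record has it"
            )
        used = [r for r in records if r.mwt_latency_min is not None]
        outcome = np.array(
            [r.ahi >= 5.0 and r.mwt_latency_min < MWT_ABNORMAL_MIN for r in used]
        )
        return used, outcome
    threshold = float(key.split(">=")[1])
    used = list(records)
    return used, np.array([r.ahi >= threshold for r in used])


# ---------------------------------------------------------------------------
# instrument registry (graded scores for overall AUCs)

def _score_tiredness(r: RespondentRecord, config: InstrumentConfig) -> int:
    if r.tiredness_freq is None:
        raise MissingDataError(f"respondent {r.id!r}: tiredness_freq missing")
    return int(r.tiredness_freq)


INSTRUMENT_SCORERS = {
    "bamsa": lambda r, c: score_bamsa(r, c),
    "stopbang": lambda r, c: score_stop_bang(r, "original", c),
    "stopbang_new": lambda r, c: score_stop_bang(r, "new", c),
    "nosas": lambda r, c: score_nosas(r, c),
    "berlin": lambda r, c: int(score_berlin(r, c).high_risk),
    "ess": lambda r, c: score_ess(r, c),
    "tiredness": _score_tiredness,
}

#: default cut-off applied when an instrument is requested without one
DEFAULT_CUTOFFS = {
    "bamsa": 4,
    "stopbang": 3,
    "stopbang_new": 3,
    "nosas": 8,
    "berlin": 1,
    "ess": 11,
    "tiredness": 3,
}


def parse_instrument_spec(spec: Union[str, Tuple[str, float]]) -> Tuple[str, float]:
    """'bamsa:4' -> ('bamsa', 4.0); bare names get their default cut-off."""
    if isinstance(spec, tuple):
        name, cutoff = spec
    elif ":" in spec:
        name, cutoff = spec.split(":", 1)
        cutoff = float(cutoff)
    else:
        name, cutoff = spec, None
    name = name.lower()
    if name not in INSTRUMENT_SCORERS:
        raise ValidationError(
            f"unknown instrument {name!r}; expected one of {sorted(INSTRUMENT_SCORERS)}"
        )
    if cutoff is None:
        cutoff = DEFAULT_CUTOFFS[name]
    return name, float(cutoff)


def instrument_scores(
    records: Sequence[RespondentRecord],
    name: str,
    config: InstrumentConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    scorer = INSTRUMENT_SCORERS[name]
    return np.array([scorer(r, config) for r in records], dtype=float)


# ---------------------------------------------------------------------------
# evaluation report

@dataclass(frozen=True)
class EvaluationRow:
    instrument: str
    cutoff: float
    label: str
    table: ConfusionTable
    summary: AccuracySummary


@dataclass(frozen=True)
class EvaluationReport:
    endpoint: str
    n: int
    n_pos: int
    rows: List[EvaluationRow]
    overall_auc: Dict[str, float]
    delong: Dict[Tuple[str, str], DelongResult]
    provenance: Dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = []
        for row in self.rows:
            s = row.summary
            pct = lambda p: None if p is None else 100.0 * p.value  # noqa: E731
            out.append(
                {
                    "label": row.label,
                    "instrument": row.instrument,
                    "cutoff": row.cutoff,
                    "TP": row.table.tp,
                    "FP": row.table.fp,
                    "FN": row.table.fn,
                    "TN": row.table.tn,
                    "SENS": pct(s.sens),
                    "SPEC": pct(s.spec),
                    "PPV": pct(s.ppv),
                    "NPV": pct(s.npv),
                    "LR+": s.lr_pos,
                    "LR-": s.lr_neg,
                    "OR": s.odds_ratio,
                    "ROC": s.roc_area_dichotomous,
                }
            )
        return pd.DataFrame(out)

    def formatted_frame(self) -> pd.DataFrame:
        """Printed-style formatting: percents to 1 decimal, ratios to 3
        significant figures, ROC areas to 3 decimals."""
        df = self.to_frame().copy()
        for col in ("SENS", "SPEC", "PPV", "NPV"):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else fmt_fixed(v, 1) + "%")
        for col in ("LR+", "LR-", "OR"):
            df[col] = df[col].map(lambda v: "" if v is None or pd.isna(v) else fmt_signif(v, 3))
        df["ROC"] = df["ROC"].map(lambda v: "" if pd.isna(v) else fmt_fixed(v, 3))
        return df


def evaluate(
    records: Sequence[RespondentRecord],
    instruments: Sequence[Union[str, Tuple[str, float]]],
    endpoint: str,
    config: InstrumentConfig = DEFAULT_CONFIG,
    compare_auc: bool = True,
) -> EvaluationReport:
    """One accuracy row per instrument/cut-off against ``endpoint``,
    with overall AUCs and pairwise DeLong comparisons per instrument.

    Raises :class:`SingleClassError` when the endpoint has no positives or
    no negatives among the usable records, and :class:`MissingDataError`
    when the endpoint needs a column the cohort lacks.
    """
    used, outcome = endpoint_outcome(records, endpoint)
    if outcome.all() or not outcome.any():
        raise SingleClassError(
            f"endpoint {endpoint!r}: outcome has a single class "
            f"({int(outcome.sum())} positives of {outcome.size})"
        )
    requests = [parse_instrument_spec(s) for s in instruments]
    names = list(dict.fromkeys(name for name, _ in requests))
    scores = {name: instrument_scores(used, name, config) for name in names}

    rows = []
    for name, cutoff in requests:
        predicted = scores[name] >= cutoff
        table = ConfusionTable.from_predictions(
            predicted, outcome, reference_label=endpoint,
            test_label=f"{name}>={cutoff:g}",
        )
        rows.append(
            EvaluationRow(
                instrument=name,
                cutoff=cutoff,
                label=f"{name} >= {cutoff:g}",
                table=table,
                summary=accuracy_metrics(table),
            )
        )

    overall = {name: auc(scores[name], outcome) for name in names}
    delong = {}
    if compare_auc:
        for a, b in combinations(names, 2):
            delong[(a, b)] = delong_compare(scores[a], scores[b], outcome)
    return EvaluationReport(
        endpoint=endpoint,
        n=int(outcome.size),
        n_pos=int(outcome.sum()),
        rows=rows,
        overall_auc=overall,
        delong=delong,
    )


# ---------------------------------------------------------------------------
# published-table verification

@dataclass(frozen=True)
class TableVerificationReport:
    results: List[RowVerification]

    @property
    def n_rows(self) -> int:
        return len(self.results)

    @property
    def n_pass(self) -> int:
        return sum(r.all_match for r in self.results)

    @property
    def failures(self) -> List[RowVerification]:
        return [r for r in self.results if not r.all_match]

    @property
    def all_pass(self) -> bool:
        return self.n_pass == self.n_rows

    def summary_frame(self) -> pd.DataFrame:
        out = []
        for r in self.results:
            out.append(
                {
                    "table": r.row.table,
                    "endpoint": r.row.endpoint,
                    "label": r.row.label,
                    "tp": r.table.tp if r.table else None,
                    "fp": r.table.fp if r.table else None,
                    "fn": r.table.fn if r.table else None,
                    "tn": r.table.tn if r.table else None,
                    "n_checked": len(r.checks),
                    "n_matched": sum(c.match for c in r.checks),
                    "pass": r.all_match,
                    "error": r.error or "",
                    "mismatches": ";".join(
                        f"{c.statistic}:{c.computed_rounded}!={c.printed}"
                        for c in r.mismatches
                    ),
                }
            )
        return pd.DataFrame(out)


def reproduce_paper_tables(
    rows: Optional[Sequence[PublishedRow]] = None,
) -> TableVerificationReport:
    """Reconstruct the 2x2 table behind every published accuracy row and
    re-derive all its printed statistics; ambiguous or inconsistent rows
    are reported, never silently resolved."""
    rows = list(rows) if rows is not None else load_published_rows()
    return TableVerificationReport(results=[reconstruct_and_verify(r) for r in rows])


# ---------------------------------------------------------------------------
# report serialization

def _markdown_table(df: pd.DataFrame) -> str:
    cells = df.astype(str).replace("nan", "").replace("None", "")
    widths = {
        c: max(len(str(c)), *(len(v) for v in cells[c])) if len(cells) else len(str(c))
        for c in cells.columns
    }
    def fmt_row(values):
        return "| " + " | ".join(str(v).ljust(widths[c]) for c, v in zip(cells.columns, values)) + " |"
    lines = [fmt_row(cells.columns), "|" + "|".join("-" * (widths[c] + 2) for c in cells.columns) + "|"]
    lines += [fmt_row(row) for row in cells.itertuples(index=False)]
    return "\n".join(lines)


def provenance_block(config: InstrumentConfig, seed: Optional[int] = None) -> Dict[str, str]:
    import scipy

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    block = {
        "bamsa_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "config_sha256": cfg_hash,
    }
    if seed is not None:
        block["seed"] = str(seed)
    return block


def render_report(
    df: pd.DataFrame,
    fmt: str = "csv",
    provenance: Optional[Dict[str, str]] = None,
) -> str:
    """Serialize a report table as csv, json or markdown with a provenance
    header (comment lines for csv/markdown, a field for json)."""
    header = [f"# {k} = {v}" for k, v in (provenance or {}).items()]
    if fmt == "csv":
        return "\n".join(header + [df.to_csv(index=False).rstrip("\n")]) + "\n"
    if fmt == "json":
        payload = {
            "provenance": provenance or {},
            "rows": json.loads(df.to_json(orient="records")),
        }
        return json.dumps(payload, indent=2) + "\n"
    if fmt == "markdown":
        return "\n".join(header + [_markdown_table(df)]) + "\n"
    raise ValidationError(f"unknown format {fmt!r}; expected csv, json or markdown")
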