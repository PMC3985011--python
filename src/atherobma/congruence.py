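"""Two-stage congruence filter over the four histology outcome indexes.

Stage 1 (index congruence): a variable counts only if the per-index BMA
runs selected it for at least one intimal-thickness index (IT mean or IT
median, radial lesion expansion) AND at least one lesional-area index (LA
mean or LA median, circumferential extension).  Variables associated with
only one lesion dimension are discarded.

Stage 2 (coefficient congruence): among stage-1 survivors, the averaged
coefficients at the supporting indexes must share a single direction of
association, and at least one must be non-negligible in magnitude
(|coefficient| >= 0.001 on the control-normalized natural-log scale the
models were fitted on).  Opposite-sign coefficients of comparable size
mark an inappropriate selection.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import OUTCOME_INDEXES

IT_INDEXES = ("IT_mean", "IT_median")
LA_INDEXES = ("LA_mean", "LA_median")

STATUS_RETAINED = "retained"
STATUS_STAGE1 = "discarded_stage1"
STATUS_SIGN = "discarded_sign"
STATUS_MAGNITUDE = "discarded_magnitude"
STATUS_PENDING = "pending"


@dataclass
class SelectionTable:
    """Per (variable, outcome index): selected flag and averaged coefficient."""

    selected: pd.DataFrame  # bool, variable x 4 indexes
    coefficients: pd.DataFrame  # float, variable x 4 indexes

    def __post_init__(self) -> None:
        for frame in (self.selected, self.coefficients):
            if list(frame.columns) != list(OUTCOME_INDEXES):
                frame_cols = list(frame.columns)
                raise ValueError(
                    f"selection table columns must be {OUTCOME_INDEXES}, got {frame_cols}"
                )
        if list(self.selected.index) != list(self.coefficients.index):
            raise ValueError("selected and coefficient tables must share variables")

    @property
    def variables(self) -> list[str]:
        return list(self.selected.index)


@dataclass(frozen=True)
class LedgerEntry:
    status: str
    direction: str  # positive / negative / n/a
    supporting: tuple[str, ...]  # indexes the variable was selected for
    coefficients: tuple[float, ...]  # aligned with `supporting`


@dataclass
class CongruenceLedger:
    """Final per-variable verdict with direction of association."""

    entries: dict[str, LedgerEntry] = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return [v for v, e in self.entries.items() if e.status == STATUS_RETAINED]

    def frame(self) -> pd.DataFrame:
        rows = []
        for var, e in self.entries.items():
            rows.append(
                {
                    "variable": var,
                    "status": e.status,
                    "direction": e.direction,
                    "supporting_indexes": "|".join(e.supporting),
                    "coefficients": "|".join(f"{c:.6g}" for c in e.coefficients),
                    "max_abs_coef": max((abs(c) for c in e.coefficients), default=0.0),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["variable", "status", "direction", "supporting_indexes",
                     "coefficients", "max_abs_coef"],
        )


def build_selection_table(results: Mapping[str, "BMAResult"]) -> SelectionTable:
    """Normalize four per-index BMA results into a selection table.

    A variable is "selected" for an index iff it appears in that result's
    retained list; its coefficient is the model-averaged slope.
    """
    missing = [i for i in OUTCOME_INDEXES if i not in results]
    if missing:
        raise ValueError(f"missing BMA results for outcome index(es): {missing}")
    variables: list[str] = []
    for index in OUTCOME_INDEXES:
        for v in results[index].names:
            if v not in variables:
                variables.append(v)
    selected = pd.DataFrame(False, index=variables, columns=list(OUTCOME_INDEXES))
    coefficients = pd.DataFrame(0.0, index=variables, columns=list(OUTCOME_INDEXES))
    for index in OUTCOME_INDEXES:
        res = results[index]
        for v in res.names:
            selected.loc[v, index] = v in res.retained
            coefficients.loc[v, index] = float(res.avg_coefficient[v])
    return SelectionTable(selected=selected, coefficients=coefficients)


def apply_index_congruence(table: SelectionTable) -> CongruenceLedger:
    """Stage 1: require selection for >= 1 IT index AND >= 1 LA index."""
    ledger = CongruenceLedger()
    for var in table.variables:
        flags = table.selected.loc[var]
        supporting = tuple(i for i in OUTCOME_INDEXES if flags[i])
        coefs = tuple(float(table.coefficients.loc[var, i]) for i in supporting)
        has_it = any(i in IT_INDEXES for i in supporting)
        has_la = any(i in LA_INDEXES for i in supporting)
        status = STATUS_PENDING if (has_it and has_la) else STATUS_STAGE1
        ledger.entries[var] = LedgerEntry(
            status=status, direction="n/a", supporting=supporting, coefficients=coefs
        )
    return ledger


def apply_coefficient_congruence(
    ledger: CongruenceLedger,
    table: SelectionTable,
    magnitude_floor: float = 0.001,
    size_ratio_cap: float = 10.0,
    strict_sign: bool = True,
) -> CongruenceLedger:
    """Stage 2: same-sign, non-negligible supporting coefficients.

    With ``strict_sign`` (default) any mix of signs among the supporting
    coefficients discards the variable.  Relaxed mode follows the
    narrower reading - only opposite signs of *comparable* size
    (max/min absolute ratio <= ``size_ratio_cap``) discard, otherwise the
    dominant coefficient sets the direction.  Variables whose supporting
    coefficients are all below ``magnitude_floor`` in absolute value are
    discarded irrespective of sign.
    """
    out = CongruenceLedger()
    for var, entry in ledger.entries.items():
        if entry.status != STATUS_PENDING:
            out.entries[var] = entry
            continue
        coefs = np.array(entry.coefficients, dtype=float)
        abs_coefs = np.abs(coefs)
        if (abs_coefs < magnitude_floor).all():
            out.entries[var] = LedgerEntry(
                STATUS_MAGNITUDE, "n/a", entry.supporting, entry.coefficients
            )
            continue
        signs = set(np.sign(coefs[abs_coefs > 0]).astype(int))
        if len(signs) > 1:
            nonzero = abs_coefs[abs_coefs > 0]
            comparable = nonzero.max() / nonzero.min() <= size_ratio_cap
            if strict_sign or comparable:
                out.entries[var] = LedgerEntry(
                    STATUS_SIGN, "n/a", entry.supporting, entry.coefficients
                )
                continue
            dominant = int(np.sign(coefs[np.argmax(abs_coefs)]))
        else:
            dominant = signs.pop()
        direction = "positive" if dominant > 0 else "negative"
        out.entries[var] = LedgerEntry(
            STATUS_RETAINED, direction, entry.supporting, entry.coefficients
        )
    return out


def run_congruence(
    results: Mapping[str, "BMAResult"],
    magnitude_floor: float = 0.001,
    size_ratio_cap: float = 10.0,
    strict_sign: bool = True,
) -> CongruenceLedger:
    """Both congruence stages from the per-index BMA results."""
    table = build_selection_table(results)
    ledger = apply_index_congruence(table)
    return apply_coefficient_congruence(
        ledger, table,
        magnitude_floor=magnitude_floor,
        size_ratio_cap=size_ratio_cap,
        strict_sign=strict_sign,
    )


def summarize_ledger(ledger: CongruenceLedger) -> pd.DataFrame:
    """Report rows: retained first, then by strongest |coefficient| descending."""
    frame = ledger.frame()
    if frame.empty:
        return frame
    frame["_retained"] = (frame["status"] != STATUS_RETAINED).astype(int)
    frame = frame.sort_values(
        by=["_retained", "max_abs_coef", "variable"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_retained")
    return frame.reset_index(drop=True)


def write_ledger(ledger: CongruenceLedger, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    summarize_ledger(ledger).to_csv(directory / "ledger.csv", index=False)


def render_report(ledger: CongruenceLedger, table: SelectionTable | None = None) -> str:
    """Human-readable markdown mirroring the selection-table presentation."""
    summary = summarize_ledger(ledger)
    lines = ["# Congruence report", ""]
    retained = summary[summary["status"] == STATUS_RETAINED]
    lines.append(f"Retained variables: {len(retained)}")
    lines.append("")
    if not summary.empty:
        lines.append("| variable | status | direction | supporting indexes | coefficients |")
        lines.append("|---|---|---|---|---|")
        for row in summary.itertuples(index=False):
            lines.append(
                f"| {row.variable} | {row.status} | {row.direction} "
                f"| {row.supporting_indexes} | {row.coefficients} |"
            )
        lines.append("")
    if table is not None:
        lines.append("## Per-index selection")
        lines.append("")
        header = "| variable | " + " | ".join(OUTCOME_INDEXES) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(OUTCOME_INDEXES) + 1))
        for var in table.variables:
            cells = []
            for idx in OUTCOME_INDEXES:
                if table.selected.loc[var, idx]:
                    cells.append(f"{table.coefficients.loc[var, idx]:+.3g}")
                else:
                    cells.append("")
            lines.append(f"| {var} | " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)
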