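"""2x2 contingency tables for drug-event pairs at PT and SOC level.

The counting unit is the report: a report contributes at most once per
event label (presence/absence) and once to the drug margin, so
``a + b + c + d = N`` holds for every label. Pair-level counting (each
report x PT pair counted) is available as an option, with the caveat
that margins then count pairs rather than reports.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .records import CleanReport


@dataclass(frozen=True)
class ContingencyTable:
    """a/b/c/d counts for one drug-event pair against the rest of the
    database view."""

    label: str
    level: str  # "PT" | "SOC"
    a: int  # target drug AND target event
    b: int  # target drug, other events
    c: int  # other drugs, target event
    d: int  # other drugs, other events

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Independence expectation E = (a+b)(a+c)/N for the a cell."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def _report_is_target(report: CleanReport, target_names: Sequence[str]) -> bool:
    targets = [t.upper() for t in target_names]
    return any(
        any(t in (de.name or "").upper() for t in targets)
        for de in report.drug_entries
    )


def _labels(report: CleanReport, level: str, counting: str):
    if level == "PT":
        labels = report.reaction_pts
    elif level == "SOC":
        labels = tuple(report.pt_soc[pt] for pt in report.reaction_pts)
    else:
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    if counting == "reports":
        return set(labels)
    if counting == "pairs":
        return list(labels)
    raise ValueError(f"counting must be 'reports' or 'pairs', got {counting!r}")


def build_tables(
    all_reports: Sequence[CleanReport],
    target_drug_names: Sequence[str],
    level: str = "PT",
    counting: str = "reports",
) -> list:
    """One table per distinct event label with a >= 1.

    ``all_reports`` is the full database view (all drugs); target-drug
    membership is decided by case-insensitive substring match against
    ``target_drug_names``.
    """
    if not all_reports:
        raise ValueError("empty database")
    event_total = Counter()
    a_counts = Counter()
    n_target = 0
    n_units = 0
    for r in all_reports:
        labels = _labels(r, level, counting)
        is_target = _report_is_target(r, target_drug_names)
        if counting == "reports":
            n_units += 1
            if is_target:
                n_target += 1
            for lab in labels:
                event_total[lab] += 1
                if is_target:
                    a_counts[lab] += 1
        else:  # pairs: margins count report x label pairs
            n_units += len(labels)
            if is_target:
                n_target += len(labels)
            for lab in labels:
                event_total[lab] += 1
                if is_target:
                    a_counts[lab] += 1

    tables = []
    for lab, a in sorted(a_counts.items()):
        b = n_target - a
        c = event_total[lab] - a
        d = n_units - a - b - c
        tables.append(ContingencyTable(label=lab, level=level, a=a, b=b, c=c, d=d))
    return tables


def event_counts(
    all_reports: Sequence[CleanReport], level: str = "PT", counting: str = "reports"
) -> pd.Series:
    """Report counts per event label, descending (the SOC ranking view)."""
    counts = Counter()
    for r in all_reports:
        for lab in _labels(r, level, counting):
            counts[lab] += 1
    s = pd.Series(counts, dtype=int).sort_values(ascending=False, kind="stable")
    s.index.name = level
    return s


def tables_to_frame(tables: Sequence[ContingencyTable]) -> pd.DataFrame:
    """TSV-ready frame with columns level,label,a,b,c,d,N."""
    return pd.DataFrame(
        [
            {"level": t.level, "label": t.label, "a": t.a, "b": t.b,
             "c": t.c, "d": t.d, "N": t.n}
            for t in tables
        ]
    )
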