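"""Read, deduplicate, and harmonise spontaneous-report data.

Two dialects are supported: FAERS-style quarterly ASCII (``$``-delimited
DEMO/DRUG/REAC/THER/OUTC tables joined on PRIMARYID) and a generic
one-row-per-record CSV dialect keyed by a report identifier (the shape
of JADER/CVARD extracts). Output is a list of :class:`~pvkit.records.RawCase`
which the primary-suspect filter turns into
:class:`~pvkit.records.CleanReport` records for the target drug.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import (
    CleanReport,
    DrugEntry,
    RawCase,
    age_to_years,
    normalize_pts,
    normalize_sex,
    parse_date,
    weight_to_kg,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A mandatory table or column is missing or malformed."""


@dataclass
class IngestLog:
    """Row-level accounting of one load: skipped and orphan rows per table."""

    skipped: Counter = field(default_factory=Counter)
    orphans: Counter = field(default_factory=Counter)
    n_cases: int = 0


_FAERS_TABLES = ("DEMO", "DRUG", "REAC", "THER", "OUTC")
_MANDATORY = ("DEMO", "DRUG", "REAC")


def _locate_tables(paths) -> dict:
    """Map table names to files, from a directory or an explicit mapping."""
    if isinstance(paths, Mapping):
        return {str(k).upper(): Path(v) for k, v in paths.items()}
    p = Path(paths)
    if p.is_dir():
        out = {}
        for f in sorted(p.iterdir()):
            stem = f.stem.upper()
            for t in _FAERS_TABLES:
                if stem.startswith(t[:4]):
                    out.setdefault(t, f)
        return out
    raise FormatError(f"{p} is not a directory or table mapping")


def _read_dollar_table(path: Path, log: IngestLog, table: str):
    """Yield dict rows of a ``$``-delimited table; malformed rows are
    counted and skipped, not fatal."""
    with open(path, encoding="utf-8", errors="replace", newline="") as fh:
        reader = csv.reader(fh, delimiter="$")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{table}: empty file {path}")
        header = [h.strip().upper() for h in header]
        for row in reader:
            if not row:
                continue
            if len(row) != len(header):
                log.skipped[table] += 1
                continue
            yield dict(zip(header, row))


def read_faers_quarter(paths) -> tuple:
    """Parse one FAERS-style quarter into raw cases.

    ``paths`` is a directory holding demo/drug/reac(/ther/outc) files or
    a mapping of table name to path. DEMO, DRUG and REAC are mandatory.
    Returns ``(cases, log)`` where ``log`` counts skipped and orphan rows.
    """
    tables = _locate_tables(paths)
    for t in _MANDATORY:
        if t not in tables:
            raise FormatError(f"mandatory table {t} not found")
    log = IngestLog()

    cases: dict = {}
    for row in _read_dollar_table(tables["DEMO"], log, "DEMO"):
        try:
            pid = row["PRIMARYID"].strip()
            cid = row.get("CASEID", pid).strip()
        except KeyError as exc:
            raise FormatError(f"DEMO header missing column {exc}")
        if not pid:
            log.skipped["DEMO"] += 1
            continue
        cases[pid] = RawCase(
            primary_id=pid,
            case_id=cid or pid,
            receipt_date=parse_date(row.get("FDA_DT")),
            event_date=parse_date(row.get("EVENT_DT")),
            sex=row.get("SEX") or None,
            age=_float_or_none(row.get("AGE")),
            age_unit=row.get("AGE_COD") or None,
            weight=_float_or_none(row.get("WT")),
            weight_unit=row.get("WT_COD") or None,
            country=row.get("REPORTER_COUNTRY") or None,
            reporter_qual=row.get("OCCP_COD") or None,
        )

    starts: dict = {}
    if "THER" in tables:
        for row in _read_dollar_table(tables["THER"], log, "THER"):
            pid = row.get("PRIMARYID", "").strip()
            seq = row.get("DSG_DRUG_SEQ", "1").strip()
            if pid not in cases:
                log.orphans["THER"] += 1
                continue
            starts[(pid, seq)] = parse_date(row.get("START_DT"))

    for row in _read_dollar_table(tables["DRUG"], log, "DRUG"):
        pid = row.get("PRIMARYID", "").strip()
        if pid not in cases:
            log.orphans["DRUG"] += 1
            continue
        seq = row.get("DRUG_SEQ", "1").strip()
        cases[pid].drugs.append(
            DrugEntry(
                name=row.get("DRUGNAME", "").strip(),
                role=_norm_role(row.get("ROLE_COD", "")),
                start_date=starts.get((pid, seq)),
            )
        )

    for row in _read_dollar_table(tables["REAC"], log, "REAC"):
        pid = row.get("PRIMARYID", "").strip()
        if pid not in cases:
            log.orphans["REAC"] += 1
            continue
        pt = row.get("PT", "").strip()
        if pt:
            cases[pid].reactions.append(pt)

    if "OUTC" in tables:
        for row in _read_dollar_table(tables["OUTC"], log, "OUTC"):
            pid = row.get("PRIMARYID", "").strip()
            if pid not in cases:
                log.orphans["OUTC"] += 1
                continue
            oc = row.get("OUTC_COD", "").strip().upper()
            if oc:
                cases[pid].outcomes.append(oc)

    log.n_cases = len(cases)
    return list(cases.values()), log


_ROLE_MAP = {"1": "PS", "2": "SS", "3": "C", "4": "I"}


def _norm_role(code: str) -> str:
    c = str(code).strip().upper()
    return _ROLE_MAP.get(c, c or "C")


def _float_or_none(v) -> Optional[float]:
    if v is None:
        return None
    s = str(v).strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def read_generic_csv(
    paths,
    key_column: str = "Report_ID",
    *,
    drug_table: str = "DRUG",
    reac_table: str = "REAC",
    demo_table: str = "DEMO",
    ther_table: str = "THER",
    outc_table: str = "OUTC",
) -> tuple:
    """Load the generic CSV dialect: one CSV per table, outer-joined on
    ``key_column``; exact-duplicate rows are dropped before the join."""
    if isinstance(paths, Mapping):
        tables = {str(k).upper(): Path(v) for k, v in paths.items()}
    else:
        p = Path(paths)
        tables = {f.stem.upper()[:4]: f for f in sorted(p.glob("*.csv"))}
    log = IngestLog()

    frames = {}
    for name, f in tables.items():
        df = pd.read_csv(f, dtype=str, keep_default_na=False)
        if key_column not in df.columns:
            raise FormatError(f"{name}: key column {key_column!r} missing in {f}")
        n0 = len(df)
        df = df.drop_duplicates()
        log.skipped[name] += n0 - len(df)
        frames[name] = df

    if demo_table not in frames:
        raise FormatError(f"mandatory table {demo_table} not found")

    cases: dict = {}
    for _, row in frames[demo_table].iterrows():
        rid = str(row[key_column]).strip()
        cases[rid] = RawCase(
            primary_id=rid,
            case_id=rid,
            receipt_date=parse_date(row.get("Receipt_Date")),
            event_date=parse_date(row.get("Event_Date")),
            sex=row.get("Sex") or None,
            age=_float_or_none(row.get("Age")),
            age_unit=row.get("Age_Unit") or None,
            weight=_float_or_none(row.get("Weight")),
            weight_unit=row.get("Weight_Unit") or None,
            country=row.get("Country") or None,
            reporter_qual=row.get("Reporter") or None,
        )

    start_by_key: dict = {}
    if ther_table in frames:
        for _, row in frames[ther_table].iterrows():
            rid = str(row[key_column]).strip()
            start_by_key[(rid, str(row.get("Drug_Name", "")).strip())] = parse_date(
                row.get("Start_Date")
            )

    if drug_table in frames:
        for _, row in frames[drug_table].iterrows():
            rid = str(row[key_column]).strip()
            case = cases.setdefault(rid, RawCase(primary_id=rid, case_id=rid))
            name = str(row.get("Drug_Name", "")).strip()
            start = parse_date(row.get("Start_Date")) or start_by_key.get((rid, name))
            case.drugs.append(
                DrugEntry(name=name, role=str(row.get("Role", "")).strip(), start_date=start)
            )

    if reac_table in frames:
        for _, row in frames[reac_table].iterrows():
            rid = str(row[key_column]).strip()
            case = cases.setdefault(rid, RawCase(primary_id=rid, case_id=rid))
            pt = str(row.get("PT", "")).strip()
            if pt:
                case.reactions.append(pt)

    if outc_table in frames:
        for _, row in frames[outc_table].iterrows():
            rid = str(row[key_column]).strip()
            if rid in cases:
                oc = str(row.get("Outcome", "")).strip().upper()
                if oc:
                    cases[rid].outcomes.append(oc)

    log.n_cases = len(cases)
    return list(cases.values()), log


# ---------------------------------------------------------------------------
# Deduplication and harmonisation


def _receipt_key(case: RawCase) -> tuple:
    d = case.receipt_date
    date_key = d.sort_key() if hasattr(d, "sort_key") else (0, 0, 0)
    try:
        pid_key = int(case.primary_id)
    except (TypeError, ValueError):
        pid_key = -1
    return (date_key, pid_key, case.primary_id)


def deduplicate(cases: Sequence[RawCase]) -> list:
    """One case per case identifier: keep the version with the latest
    receipt date, ties broken by the numerically larger primary id."""
    best: dict = {}
    for c in cases:
        key = c.case_id
        if key not in best or _receipt_key(c) > _receipt_key(best[key]):
            best[key] = c
    removed = len(cases) - len(best)
    if removed:
        logger.info("deduplicate: removed %d duplicate case versions", removed)
    return list(best.values())


def match_drug_names(case: RawCase, names: Sequence[str]) -> list:
    """Case-insensitive substring match of any target name against the
    verbatim drug-name field; one boolean per drug entry."""
    if not names:
        raise ValueError("names must be nonempty")
    targets = [n.upper() for n in names]
    return [any(t in (de.name or "").upper() for t in targets) for de in case.drugs]


def to_clean_report(case: RawCase) -> CleanReport:
    """Harmonise one raw case into a CleanReport (units, codes, PT dedup)."""
    return CleanReport(
        report_id=case.primary_id,
        sex=normalize_sex(case.sex),
        age_years=age_to_years(case.age, case.age_unit),
        weight_kg=weight_to_kg(case.weight, case.weight_unit),
        outcome_codes=tuple(dict.fromkeys(o.upper() for o in case.outcomes)),
        drug_entries=list(case.drugs),
        reaction_pts=normalize_pts(case.reactions),
        event_date=case.event_date,
        country=case.country,
        indications=tuple(dict.fromkeys(str(i).upper() for i in case.indications)),
    )


def filter_primary_suspect(
    cases: Sequence[RawCase],
    names: Sequence[str],
    ps_roles: Iterable[str] = ("PS",),
) -> list:
    """Retain deduplicated cases with >=1 drug entry matching a target
    name whose role is primary suspect, harmonised to CleanReport.

    ``ps_roles`` is configurable for dialects whose role column carries a
    different vocabulary (e.g. "suspected drug").
    """
    roles = {str(r).upper() for r in ps_roles}
    out = []
    for case in cases:
        matches = match_drug_names(case, names)
        if any(
            m and (de.role or "").upper() in roles
            for m, de in zip(matches, case.drugs)
        ):
            clean = to_clean_report(case)
            if clean.reaction_pts:
                out.append(clean)
    return out


# ---------------------------------------------------------------------------
# Term map (PT -> primary SOC)


def load_term_map(path) -> dict:
    """Load a 2-column CSV (PT, SOC) as a PT->SOC mapping.

    Each PT must map to exactly one SOC (primary-SOC convention);
    a PT repeated with a different SOC is a format error.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("term map must have two columns (PT, SOC)")
    tm: dict = {}
    for pt, soc in zip(df.iloc[:, 0], df.iloc[:, 1]):
        key = str(pt).strip().upper()
        val = str(soc).strip()
        if key in tm and tm[key] != val:
            raise FormatError(f"PT {key!r} maps to multiple SOCs")
        tm[key] = val
    return tm


UNMAPPED = "UNMAPPED"


def map_pt_to_soc(reports: Sequence[CleanReport], term_map: Mapping[str, str]) -> tuple:
    """Annotate every report's PTs with their SOC.

    PTs absent from the map are annotated :data:`UNMAPPED` and counted.
    Returns ``(reports, n_unmapped)``; annotation is stored on
    ``report.pt_soc``.
    """
    if not term_map:
        raise ValueError("term_map is empty")
    n_unmapped = 0
    for r in reports:
        ann = {}
        for pt in r.reaction_pts:
            soc = term_map.get(pt)
            if soc is None:
                soc = UNMAPPED
                n_unmapped += 1
            ann[pt] = soc
        r.pt_soc = ann
    if n_unmapped:
        logger.info("map_pt_to_soc: %d PT occurrences unmapped", n_unmapped)
    return list(reports), n_unmapped


# ---------------------------------------------------------------------------
# Demographic summary


def _band_age(age: Optional[float], cuts: Sequence[float]) -> str:
    if age is None:
        return "Unknown"
    lo, hi = cuts
    if age < lo:
        return f"<{lo:g}"
    if age <= hi:
        return f"{lo:g}–{hi:g}"
    return f">{hi:g}"


def _band_weight(w: Optional[float], cuts: Sequence[float]) -> str:
    if w is None:
        return "Unknown"
    lo, hi = cuts
    if w < lo:
        return f"<{lo:g}"
    if w <= hi:
        return f"{lo:g}–{hi:g}"
    return f">{hi:g}"


def _tally(counter: Counter, order: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Counts plus percentages of the tally total (the denominator each
    characteristic's table uses; for multi-valued characteristics this
    exceeds the report count)."""
    total = sum(counter.values())
    if order is None:
        items = counter.most_common()
    else:
        items = [(k, counter.get(k, 0)) for k in order]
    df = pd.DataFrame(items, columns=["category", "count"])
    df["pct"] = 100.0 * df["count"] / total if total else 0.0
    return df


def summarize_demographics(
    reports: Sequence[CleanReport],
    age_cuts: Sequence[float] = (18, 65),
    weight_cuts: Sequence[float] = (50, 100),
    top_k: int = 5,
) -> dict:
    """Counts and percentages by sex, age band, weight band, outcome,
    top-k countries and indications.

    ``age_cuts=(15, 65)`` reproduces the JADER banding variant.
    """
    sex = Counter()
    age = Counter()
    weight = Counter()
    outcome = Counter()
    country = Counter()
    indication = Counter()
    for r in reports:
        sex[r.sex.capitalize() if r.sex != "unknown" else "Unknown"] += 1
        age[_band_age(r.age_years, age_cuts)] += 1
        weight[_band_weight(r.weight_kg, weight_cuts)] += 1
        if r.outcome_codes:
            for oc in r.outcome_codes:
                outcome[oc] += 1
        else:
            outcome["Unknown"] += 1
        country[r.country if r.country else "Unknown"] += 1
        for ind in r.indications:
            indication[ind] += 1

    lo, hi = age_cuts
    age_order = [f"<{lo:g}", f"{lo:g}–{hi:g}", f">{hi:g}", "Unknown"]
    wlo, whi = weight_cuts
    weight_order = [f"<{wlo:g}", f"{wlo:g}–{whi:g}", f">{whi:g}", "Unknown"]
    return {
        "sex": _tally(sex, ["Female", "Male", "Unknown"]),
        "age": _tally(age, age_order),
        "weight": _tally(weight, weight_order),
        "outcome": _tally(outcome),
        "country": _tally(country).head(top_k).reset_index(drop=True),
        "indication": _tally(indication).head(top_k).reset_index(drop=True),
        "n_reports": len(reports),
    }
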