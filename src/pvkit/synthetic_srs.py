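"""Synthetic spontaneous-reporting-system cohorts with known ground truth.

Emulates the data regime of a passive pharmacovigilance database: many
drugs by many events with multinomial background reporting, designated
drug–event pairs with elevated relative risk, demographic fields with
high missingness, partial/invalid dates, duplicate case versions, and
Weibull-distributed onset times. Every distributional choice is a
stand-in for an undocumented real-world process and is recorded in the
cohort's ``truth`` metadata so downstream stages can be tested against
known answers.
"""

from __future__ import annotations

import copy
import csv
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Tuple

import numpy as np

from .records import DrugEntry, PartialDate, RawCase

_DEFAULT_MISSINGNESS = {"sex": 0.12, "age": 0.20, "weight": 0.70, "country": 0.05}

_COUNTRIES = ("US", "FR", "JP", "CN", "DE", "CA", "GB", "IT")
_OUTCOMES = ("HO", "DE", "OT", "LT", "DS", "RI")
_OUTCOME_P = (0.30, 0.25, 0.25, 0.12, 0.05, 0.03)


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``signal_pairs`` plants disproportionality: for each
    ``(drug_index, event_index, rr)`` the event's probability conditional
    on the drug is multiplied by ``rr`` and the row renormalised, so the
    realised marginal relative risk differs slightly from the multiplier.
    Onset times are Weibull(``onset_shape``, ``onset_scale``) days; the
    defaults (0.8, 10) give a median near 6 days with a decreasing
    hazard, the early-failure regime typical of anti-infective ADEs.
    """

    n_reports: int = 50_000
    n_drugs: int = 20
    n_events: int = 100
    signal_pairs: Tuple[Tuple[int, int, float], ...] = ()
    events_per_report: Tuple[int, int] = (1, 3)
    onset_shape: float = 0.8
    onset_scale: float = 10.0
    p_duplicate: float = 0.10
    p_bad_date: float = 0.20
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ConfigurationError("n_reports must be >= 0")
        if self.n_drugs < 1 or self.n_events < 1:
            raise ConfigurationError("n_drugs and n_events must be positive")
        lo, hi = self.events_per_report
        if not (1 <= lo <= hi <= self.n_events):
            raise ConfigurationError(
                f"events_per_report range {self.events_per_report} invalid"
            )
        if self.onset_shape <= 0 or self.onset_scale <= 0:
            raise ConfigurationError("Weibull parameters must be positive")
        for name in ("p_duplicate", "p_bad_date"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        for k, v in self.missingness.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"missingness[{k}]={v} outside [0,1]")
        for d, e, rr in self.signal_pairs:
            if not (0 <= d < self.n_drugs and 0 <= e < self.n_events):
                raise ConfigurationError(f"signal pair ({d},{e}) out of range")
            if rr < 0:
                raise ConfigurationError("relative-risk multiplier must be >= 0")

    def drug_name(self, i: int) -> str:
        return f"DRUG{i:03d}"

    def pt_name(self, j: int) -> str:
        return f"PT{j:04d}"


@dataclass
class SyntheticCohort:
    """Generated reports (pre-dedup: may contain duplicate case versions)
    plus the ground truth used to generate them."""

    reports: list  # list[RawCase]
    truth: dict


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage
    return np.random.default_rng([config.seed % (2**31), stream])


def generate_reports(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort of single-drug reports from the configured model.

    Each report carries one drug (role PS, matching the primary-suspect
    restriction of the analyses this feeds), 1–k distinct reaction PTs
    drawn from an event multinomial whose probabilities are tilted for
    planted signal pairs, complete therapy-start/event/receipt dates, and
    demographics masked per the missingness fractions.
    """
    rng = _rng(config, 0)
    n = config.n_reports
    E = config.n_events

    # Background event probabilities: one Dirichlet(1) draw per config so
    # event margins vary realistically across labels.
    event_base = rng.dirichlet(np.ones(E))

    truth = {
        "signal_pairs": tuple(config.signal_pairs),
        "event_base": event_base,
        "onset_shape": config.onset_shape,
        "onset_scale": config.onset_scale,
        "n_cases": n,
        "drug_names": tuple(config.drug_name(i) for i in range(config.n_drugs)),
        "pt_names": tuple(config.pt_name(j) for j in range(E)),
        "duplicated_case_ids": set(),
        "corrupted": {},
        "note": "distributional choices are synthetic stand-ins; see truth keys",
    }
    if n == 0:
        return SyntheticCohort(reports=[], truth=truth)

    drugs = rng.integers(0, config.n_drugs, size=n)
    lo, hi = config.events_per_report
    n_ev = rng.integers(lo, hi + 1, size=n)

    # Per-report event log-weights: base, tilted for signal pairs.
    logp = np.log(event_base)[None, :].repeat(n, axis=0)
    for d, e, rr in config.signal_pairs:
        mask = drugs == d
        if rr == 0:
            logp[mask, e] = -np.inf
        else:
            logp[mask, e] += np.log(rr)
    # Gumbel top-k trick: sampling without replacement from the
    # renormalised row distribution (shift-invariant, so no explicit
    # renormalisation needed).
    gumbel = rng.gumbel(size=(n, E))
    perturbed = logp + gumbel
    kmax = hi
    top = np.argpartition(-perturbed, kmax - 1 if kmax > 1 else 0, axis=1)[:, :kmax]
    # order the retained slots so truncation to n_ev keeps the best ones
    order = np.argsort(-np.take_along_axis(perturbed, top, axis=1), axis=1)
    top = np.take_along_axis(top, order, axis=1)

    # Dates: therapy start uniform over 2004–2023, onset Weibull days,
    # receipt lags the event by a reporting delay.
    d0 = _dt.date(2004, 1, 1).toordinal()
    d1 = _dt.date(2023, 12, 31).toordinal()
    start_ord = rng.integers(d0, d1 + 1, size=n)
    onset = config.onset_scale * rng.weibull(config.onset_shape, size=n)
    onset_days = np.round(onset).astype(int)
    event_ord = start_ord + onset_days
    receipt_ord = event_ord + rng.integers(2, 180, size=n)

    sex = rng.choice(np.array(["F", "M"]), size=n, p=[0.45, 0.55])
    age = np.clip(rng.normal(55.0, 20.0, size=n), 0.0, 95.0).round(1)
    weight = np.clip(rng.normal(70.0, 15.0, size=n), 2.0, 200.0).round(1)
    country = rng.choice(np.array(_COUNTRIES), size=n)
    outcome = rng.choice(np.array(_OUTCOMES), size=n, p=_OUTCOME_P)
    miss = {
        k: rng.random(n) < config.missingness.get(k, 0.0)
        for k in ("sex", "age", "weight", "country")
    }
    indication = rng.choice(
        np.array(
            ["FUNGAL INFECTION", "FEBRILE NEUTROPENIA", "ANTIFUNGAL PROPHYLAXIS",
             "PNEUMONIA", "SEPSIS"]
        ),
        size=n,
        p=[0.35, 0.2, 0.2, 0.15, 0.1],
    )

    reports = []
    for i in range(n):
        case_id = str(1_000_000 + i)
        start = PartialDate.from_date(_dt.date.fromordinal(int(start_ord[i])))
        reports.append(
            RawCase(
                primary_id=case_id + "1",
                case_id=case_id,
                receipt_date=PartialDate.from_date(
                    _dt.date.fromordinal(int(receipt_ord[i]))
                ),
                event_date=PartialDate.from_date(
                    _dt.date.fromordinal(int(event_ord[i]))
                ),
                sex=None if miss["sex"][i] else str(sex[i]),
                age=None if miss["age"][i] else float(age[i]),
                age_unit=None if miss["age"][i] else "YR",
                weight=None if miss["weight"][i] else float(weight[i]),
                weight_unit=None if miss["weight"][i] else "KG",
                country=None if miss["country"][i] else str(country[i]),
                reporter_qual="MD",
                drugs=[
                    DrugEntry(
                        name=config.drug_name(int(drugs[i])),
                        role="PS",
                        start_date=start,
                    )
                ],
                reactions=[config.pt_name(int(j)) for j in top[i, : n_ev[i]]],
                outcomes=[str(outcome[i])],
                indications=[str(indication[i])],
            )
        )
    return SyntheticCohort(reports=reports, truth=truth)


def generate_onsets(config: SimulationConfig, n: int) -> np.ndarray:
    """``n`` strictly positive Weibull(shape, scale) onset times in days."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(config, 3)
    out = config.onset_scale * rng.weibull(config.onset_shape, size=n)
    while np.any(out <= 0.0):  # guard against underflow to exactly 0
        bad = out <= 0.0
        out[bad] = config.onset_scale * rng.weibull(config.onset_shape, size=bad.sum())
    return out


def inject_duplicates(
    cohort: SyntheticCohort, config: SimulationConfig
) -> SyntheticCohort:
    """Give a fraction ``p_duplicate`` of cases 1–2 extra versions.

    Extra versions share the case identifier, get strictly later receipt
    dates and a numerically larger primary id, and may carry a modified
    reaction list — the pattern the deduplication rule must undo. Truth
    keeps the original case count.
    """
    if config.p_duplicate == 0 or not cohort.reports:
        return cohort
    rng = _rng(config, 1)
    n = len(cohort.reports)
    n_dup = int(round(config.p_duplicate * n))
    idx = rng.choice(n, size=n_dup, replace=False)
    reports = list(cohort.reports)
    truth = dict(cohort.truth)
    truth["duplicated_case_ids"] = set()
    pt_names = truth.get("pt_names", ())
    for i in sorted(int(j) for j in idx):
        base = reports[i]
        truth["duplicated_case_ids"].add(base.case_id)
        n_versions = int(rng.integers(1, 3))
        receipt = base.receipt_date
        for v in range(n_versions):
            dup = copy.deepcopy(base)
            dup.primary_id = base.case_id + str(2 + v)
            lag = int(rng.integers(5, 61))
            receipt = PartialDate.from_date(
                _dt.date.fromordinal(receipt.to_date().toordinal() + lag)
            )
            dup.receipt_date = receipt
            if rng.random() < 0.5:
                if len(dup.reactions) > 1 and rng.random() < 0.5:
                    dup.reactions = dup.reactions[:-1]
                elif pt_names:
                    extra = str(pt_names[int(rng.integers(len(pt_names)))])
                    if extra not in dup.reactions:
                        dup.reactions = dup.reactions + [extra]
            reports.append(dup)
    return SyntheticCohort(reports=reports, truth=truth)


def corrupt_dates(
    cohort: SyntheticCohort, config: SimulationConfig
) -> SyntheticCohort:
    """Degrade the dates of a fraction ``p_bad_date`` of reports.

    Corruption kinds: event date truncated to year or year-month, event
    or therapy-start date removed, or dates inverted (event strictly
    before start). All kinds make the report an exclusion for
    time-to-onset; the affected ids and kinds are recorded in truth.
    """
    if config.p_bad_date == 0 or not cohort.reports:
        truth = dict(cohort.truth)
        truth.setdefault("corrupted", {})
        return SyntheticCohort(reports=cohort.reports, truth=truth)
    rng = _rng(config, 2)
    n = len(cohort.reports)
    n_bad = int(round(config.p_bad_date * n))
    idx = rng.choice(n, size=n_bad, replace=False)
    kinds = ("year_only", "year_month", "missing_event", "missing_start", "inverted")
    reports = [copy.deepcopy(r) for r in cohort.reports]
    truth = dict(cohort.truth)
    corrupted = {}
    for i in sorted(int(j) for j in idx):
        r = reports[i]
        kind = str(rng.choice(kinds))
        ev = r.event_date
        if kind == "year_only" and isinstance(ev, PartialDate):
            r.event_date = PartialDate(ev.year)
        elif kind == "year_month" and isinstance(ev, PartialDate):
            r.event_date = PartialDate(ev.year, ev.month)
        elif kind == "missing_event":
            r.event_date = None
        elif kind == "missing_start":
            for de in r.drugs:
                de.start_date = None
        elif kind == "inverted":
            start = r.drugs[0].start_date if r.drugs else None
            if isinstance(start, PartialDate) and start.is_complete:
                back = int(rng.integers(1, 30))
                r.event_date = PartialDate.from_date(
                    _dt.date.fromordinal(start.to_date().toordinal() - back)
                )
            else:
                r.event_date = None
                kind = "missing_event"
        corrupted[r.primary_id] = kind
    truth["corrupted"] = corrupted
    return SyntheticCohort(reports=reports, truth=truth)


# ---------------------------------------------------------------------------
# Writers

_FAERS_FILES = {
    "DEMO": "demo.txt",
    "DRUG": "drug.txt",
    "REAC": "reac.txt",
    "THER": "ther.txt",
    "OUTC": "outc.txt",
}
_GENERIC_FILES = {
    "DEMO": "demo.csv",
    "DRUG": "drug.csv",
    "REAC": "reac.csv",
    "THER": "ther.csv",
    "OUTC": "outc.csv",
}


def _fmt_date(d) -> str:
    return d.to_faers() if isinstance(d, PartialDate) else ""


def _fmt(v) -> str:
    return "" if v is None else str(v)


def write_srs(cohort: SyntheticCohort, dialect: str, path) -> dict:
    """Write a cohort as FAERS-style ``$``-delimited ASCII or generic CSV.

    Returns the mapping of table name to file path. ``read`` of the
    written files reproduces the cohort field-for-field (on populated
    fields).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if dialect == "faers_ascii":
        return _write_faers(cohort, path)
    if dialect == "generic_csv":
        return _write_generic(cohort, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_faers(cohort: SyntheticCohort, path: Path) -> dict:
    files = {k: path / v for k, v in _FAERS_FILES.items()}

    def w(fh, row):
        fh.write("$".join(row) + "\n")

    with open(files["DEMO"], "w", encoding="utf-8", newline="") as fh:
        w(fh, ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE",
               "AGE_COD", "WT", "WT_COD", "REPORTER_COUNTRY", "OCCP_COD"])
        for r in cohort.reports:
            w(fh, [r.primary_id, r.case_id, _fmt_date(r.receipt_date),
                   _fmt_date(r.event_date), _fmt(r.sex), _fmt(r.age),
                   _fmt(r.age_unit), _fmt(r.weight), _fmt(r.weight_unit),
                   _fmt(r.country), _fmt(r.reporter_qual)])
    with open(files["DRUG"], "w", encoding="utf-8", newline="") as fh:
        w(fh, ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"])
        for r in cohort.reports:
            for seq, de in enumerate(r.drugs, start=1):
                w(fh, [r.primary_id, r.case_id, str(seq), de.role, de.name])
    with open(files["REAC"], "w", encoding="utf-8", newline="") as fh:
        w(fh, ["PRIMARYID", "CASEID", "PT"])
        for r in cohort.reports:
            for pt in r.reactions:
                w(fh, [r.primary_id, r.case_id, pt])
    with open(files["THER"], "w", encoding="utf-8", newline="") as fh:
        w(fh, ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"])
        for r in cohort.reports:
            for seq, de in enumerate(r.drugs, start=1):
                w(fh, [r.primary_id, r.case_id, str(seq), _fmt_date(de.start_date)])
    with open(files["OUTC"], "w", encoding="utf-8", newline="") as fh:
        w(fh, ["PRIMARYID", "CASEID", "OUTC_COD"])
        for r in cohort.reports:
            for oc in r.outcomes:
                w(fh, [r.primary_id, r.case_id, oc])
    return files


def _write_generic(cohort: SyntheticCohort, path: Path) -> dict:
    files = {k: path / v for k, v in _GENERIC_FILES.items()}
    with open(files["DEMO"], "w", encoding="utf-8", newline="") as fh:
        cw = csv.writer(fh)
        cw.writerow(["Report_ID", "Receipt_Date", "Event_Date", "Sex", "Age",
                     "Age_Unit", "Weight", "Weight_Unit", "Country", "Reporter"])
        for r in cohort.reports:
            cw.writerow([r.primary_id, _fmt_date(r.receipt_date),
                         _fmt_date(r.event_date), _fmt(r.sex), _fmt(r.age),
                         _fmt(r.age_unit), _fmt(r.weight), _fmt(r.weight_unit),
                         _fmt(r.country), _fmt(r.reporter_qual)])
    with open(files["DRUG"], "w", encoding="utf-8", newline="") as fh:
        cw = csv.writer(fh)
        cw.writerow(["Report_ID", "Drug_Name", "Role", "Start_Date"])
        for r in cohort.reports:
            for de in r.drugs:
                cw.writerow([r.primary_id, de.name, de.role, _fmt_date(de.start_date)])
    with open(files["REAC"], "w", encoding="utf-8", newline="") as fh:
        cw = csv.writer(fh)
        cw.writerow(["Report_ID", "PT"])
        for r in cohort.reports:
            for pt in r.reactions:
                cw.writerow([r.primary_id, pt])
    with open(files["THER"], "w", encoding="utf-8", newline="") as fh:
        cw = csv.writer(fh)
        cw.writerow(["Report_ID", "Drug_Name", "Start_Date"])
        for r in cohort.reports:
            for de in r.drugs:
                cw.writerow([r.primary_id, de.name, _fmt_date(de.start_date)])
    with open(files["OUTC"], "w", encoding="utf-8", newline="") as fh:
        cw = csv.writer(fh)
        cw.writerow(["Report_ID", "Outcome"])
        for r in cohort.reports:
            for oc in r.outcomes:
                cw.writerow([r.primary_id, oc])
    return files
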