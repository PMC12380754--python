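"""Positivity thresholds, consensus classification, exclusions, overlap.

A drug-event pair is flagged per algorithm by the standard published
criteria (all configurable):

* ROR:   a >= 3 and ROR 95% CI lower bound > 1
* PRR:   PRR >= 2 and chi-squared >= 4 and a >= 3
* BCPNN: IC025 > 0
* MGPS:  EBGM05 >= 2

At PT level a pair is *significant* only when all four algorithms flag
it (optionally gated on the Bonferroni-adjusted chi-squared p); at SOC
level a label meeting at least one criterion is *positive* and one
meeting all four is *significant*.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import pandas as pd


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-algorithm positivity thresholds and the Bonferroni gate."""

    ror_a_min: int = 3
    ror_ci_low_min: float = 1.0  # strict >
    prr_min: float = 2.0
    chi2_min: float = 4.0
    prr_a_min: int = 3
    ic025_min: float = 0.0  # strict >
    ebgm05_min: float = 2.0  # inclusive >=
    use_bonferroni: bool = True  # PT level only
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.ror_a_min < 1 or self.prr_a_min < 1:
            raise ValueError("a_min thresholds must be >= 1")


@dataclass
class SignalVerdict:
    """Per-algorithm flags and the consensus classification for one label."""

    label: str
    level: str
    ror_flag: bool
    prr_flag: bool
    bcpnn_flag: bool
    mgps_flag: bool
    classification: str  # significant | positive | negative
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    @property
    def n_positive_algorithms(self) -> int:
        return sum((self.ror_flag, self.prr_flag, self.bcpnn_flag, self.mgps_flag))


def _flags(row, policy: ThresholdPolicy):
    a = row["a"]
    ror_flag = bool(
        a >= policy.ror_a_min
        and row["ror_ci_low"] == row["ror_ci_low"]  # not NaN
        and row["ror_ci_low"] > policy.ror_ci_low_min
    )
    prr_flag = bool(
        a >= policy.prr_a_min
        and row["prr"] == row["prr"]
        and row["prr"] >= policy.prr_min
        and row["chi2"] >= policy.chi2_min
    )
    bcpnn_flag = bool(row["ic025"] > policy.ic025_min)
    mgps_flag = bool(row["ebgm05"] >= policy.ebgm05_min)
    return ror_flag, prr_flag, bcpnn_flag, mgps_flag


def classify(
    stats_row: Mapping, policy: ThresholdPolicy, level: str
) -> SignalVerdict:
    """Classify one label from its statistics row.

    PT level: significant iff all four flags (and, with the Bonferroni
    gate, p_adj < alpha); otherwise negative. SOC level: significant iff
    all four, positive iff at least one, else negative.
    """
    rf, pf, bf, mf = _flags(stats_row, policy)
    all_four = rf and pf and bf and mf
    if level == "PT":
        sig = all_four
        if sig and policy.use_bonferroni:
            sig = stats_row["p_adj"] < policy.alpha
        classification = "significant" if sig else "negative"
    elif level == "SOC":
        if all_four:
            classification = "significant"
        elif rf or pf or bf or mf:
            classification = "positive"
        else:
            classification = "negative"
    else:
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    return SignalVerdict(
        label=stats_row["label"],
        level=level,
        ror_flag=rf,
        prr_flag=pf,
        bcpnn_flag=bf,
        mgps_flag=mf,
        classification=classification,
    )


def classify_table(
    stats: pd.DataFrame, policy: ThresholdPolicy, level: str
) -> pd.DataFrame:
    """Vector version of :func:`classify` over a signal-statistics frame."""
    verdicts = [classify(row, policy, level) for _, row in stats.iterrows()]
    return pd.DataFrame(
        [
            {
                "label": v.label,
                "level": v.level,
                "ror_flag": v.ror_flag,
                "prr_flag": v.prr_flag,
                "bcpnn_flag": v.bcpnn_flag,
                "mgps_flag": v.mgps_flag,
                "n_positive_algorithms": v.n_positive_algorithms,
                "classification": v.classification,
                "excluded": v.excluded,
                "exclusion_reason": v.exclusion_reason,
            }
            for v in verdicts
        ]
    )


def parse_blocklist(lines) -> list:
    """Parse blocklist entries ``PATTERN[<tab>reason]`` into
    (glob pattern, reason) pairs; blank lines and ``#`` comments skipped."""
    out = []
    for line in lines:
        s = str(line).strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split("\t")
        pattern = parts[0].strip()
        if not pattern:
            raise ValueError(f"malformed blocklist entry: {line!r}")
        reason = parts[1].strip() if len(parts) > 1 and parts[1].strip() else "excluded"
        out.append((pattern, reason))
    return out


def apply_exclusions(verdicts: pd.DataFrame, blocklist: Sequence) -> pd.DataFrame:
    """Mark labels matching any case-insensitive glob pattern as excluded
    with the pattern's reason tag. Rows are marked, never dropped.

    ``blocklist`` entries are (pattern, reason) pairs or bare patterns.
    """
    pairs = []
    for entry in blocklist:
        if isinstance(entry, str):
            pairs.append((entry, "excluded"))
        else:
            pattern, reason = entry
            if not str(pattern).strip():
                raise ValueError(f"malformed blocklist pattern: {entry!r}")
            pairs.append((str(pattern), str(reason)))
    out = verdicts.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
        out["exclusion_reason"] = None
    for i, label in zip(out.index, out["label"]):
        lab = str(label).upper()
        for pattern, reason in pairs:
            if fnmatch.fnmatchcase(lab, pattern.upper()):
                out.loc[i, "excluded"] = True
                out.loc[i, "exclusion_reason"] = reason
                break
    return out


def overlap(signal_sets: Mapping[str, set]) -> dict:
    """Venn decomposition of named label sets.

    For every nonempty subset of set names, the labels exclusive to
    exactly that subset (i.e. in all of its members and in none of the
    others). Returns ``{"regions": {names-tuple: sorted labels},
    "counts": {...}, "union_size": int}``; region sizes sum to the size
    of the union.
    """
    if len(signal_sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(signal_sets)
    sets = {k: set(signal_sets[k]) for k in names}
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[k] for k in combo))
            outside = set.union(
                *(sets[k] for k in names if k not in combo), set()
            ) if len(combo) < len(names) else set()
            exclusive = inside - outside
            regions[combo] = sorted(exclusive)
    union = set.union(*sets.values())
    return {
        "regions": regions,
        "counts": {combo: len(labels) for combo, labels in regions.items()},
        "union_size": len(union),
    }
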