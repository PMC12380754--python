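# pvkit

**Pharmacovigilance signal detection on spontaneous-report data.**

Spontaneous reporting systems (FAERS, JADER, CVARD, …) collect voluntary
adverse-drug-event (ADE) reports. `pvkit` implements the standard
workflow for mining them for a single drug of interest: ingestion and
FDA-style deduplication, 2×2 contingency construction per drug–event
pair, four-algorithm disproportionality analysis with consensus
screening, time-to-onset (TTO) modelling, and the set/graph/enrichment
mechanics used in network-pharmacology follow-up of a detected toxicity.
A synthetic-cohort generator with known ground truth (planted relative
risks, duplicate rates, corrupted dates, Weibull onset times) makes the
whole pipeline testable without access to the real databases.

## The statistics

For each event label (MedDRA preferred term, PT, or system organ class,
SOC) the database is collapsed into the 2×2 report table

|              | target event | other events |
|--------------|--------------|--------------|
| target drug  | a            | b            |
| other drugs  | c            | d            |

with N = a+b+c+d and independence expectation E = (a+b)(a+c)/N. Four
disproportionality statistics are computed per label:

- **ROR** = ad/bc with Wald 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
  Haldane–Anscombe +0.5 on all cells when any cell is zero.
- **PRR** = [a/(a+b)]/[c/(c+d)] with the Pearson χ²₁ statistic
  N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)] (Yates variant available) and its
  upper-tail p, optionally Bonferroni-adjusted across labels.
- **BCPNN information component** IC = log₂ of the shrunken
  observed/expected co-reporting ratio in closed form
  (priors α₁=β₁=γ₁₁=1, α=β=2), with IC025 = E(IC) − 2√V(IC).
- **MGPS/EBGM**: the relative reporting rate λ gets a two-component
  gamma mixture prior fitted by marginal (negative-binomial) maximum
  likelihood across all labels; per label the posterior is again a
  gamma mixture, EBGM = exp E[ln λ | a] and EBGM05 is the posterior
  5th percentile.

A pair is flagged per algorithm at the standard thresholds
(a≥3 & ROR CI low>1; PRR≥2 & χ²≥4 & a≥3; IC025>0; EBGM05≥2, all
configurable) and called **significant** when all four flag it — at PT
level optionally gated on the Bonferroni-adjusted χ² p-value. Onset
times get Weibull maximum likelihood with Wald CIs on the log-parameter
scale; a shape 95% CI entirely below 1 indicates a decreasing hazard
("early failure" — ADEs concentrate early in therapy).

## Worked example

Generate a 20,000-report cohort with one planted drug–event pair at
relative risk 8, push it through the full pipeline, and check that only
the planted pair survives the four-algorithm consensus:

```python
from pvkit.synthetic_srs import (SimulationConfig, generate_reports,
                                 inject_duplicates, corrupt_dates, write_srs)
from pvkit import srs_io, contingency, dispro, screening, tto

cfg = SimulationConfig(n_reports=20_000, n_drugs=5, n_events=50,
                       signal_pairs=((0, 7, 8.0),), seed=42)
cohort = corrupt_dates(inject_duplicates(generate_reports(cfg), cfg), cfg)
write_srs(cohort, "faers_ascii", "srs_data")

cases, log = srs_io.read_faers_quarter("srs_data")
deduped = srs_io.deduplicate(cases)
reports = [srs_io.to_clean_report(c) for c in deduped]

tables = contingency.build_tables(reports, ["DRUG000"], level="PT")
stats = dispro.signal_table(tables)
verdicts = screening.classify_table(stats, screening.ThresholdPolicy(), "PT")

ps = srs_io.filter_primary_suspect(deduped, ["DRUG000"])
records, excl = tto.compute_tto(ps, ["DRUG000"])
fit = tto.weibull_fit(records["days"].to_numpy())
```

Output (printed by the snippet above with a few f-strings):

```
23019 report versions -> 20000 cases after dedup
planted pair PT0007: a=2406, ROR=8.70 (8.06-9.39), PRR=4.13, IC025=1.26, EBGM05=2.50
consensus: significant
significant labels: ['PT0007']
TTO: 3246 valid / 804 excluded; median 7 d (IQR 13); Weibull shape 0.86 (95% CI 0.84-0.89) -> early_failure
```

Reading this: deduplication removed the 3,019 injected duplicate case
versions exactly; the planted pair is the only label passing all four
algorithms (ROR 8.70 near the planted multiplier, EBGM05 2.50 above the
≥2 threshold); reports with corrupted dates were excluded from TTO with
reasons, and the Weibull shape CI (0.84–0.89) sits below 1, classifying
the onset profile as early failure — consistent with the generator's
shape-0.8 onset model.

The same flow is scriptable from the shell:

```bash
pvkit simulate --config cfg.yaml --dialect faers_ascii --out DIR --seed 42
pvkit signals  --input DIR --drug DRUG000 --out signals.tsv
pvkit screen   --signals signals.tsv --blocklist bl.txt --out verdicts.tsv
pvkit tto      --input DIR --drug DRUG000 --out tto/
pvkit netpharm --drug-targets t.txt --disease-genes d.txt --edges ppi.tsv --out np/
```

## Layout

- `pvkit.synthetic_srs` — ground-truth cohort generator and writers
- `pvkit.srs_io` — FAERS-ASCII / generic-CSV readers, dedup, PS filter,
  PT→SOC mapping, demographic summaries
- `pvkit.contingency` — 2×2 tables at PT/SOC level
- `pvkit.dispro` — ROR, PRR+χ², BCPNN, MGPS/EBGM, Bonferroni
- `pvkit.screening` — thresholds, consensus, exclusion lists, Venn overlap
- `pvkit.tto` — onset computation, summaries, binning, Weibull MLE,
  Kruskal–Wallis, Kaplan–Meier
- `pvkit.netpharm` — gene-set intersection, PPI filtering, betweenness
  hubs, hypergeometric over-representation

See `docs/methods.md` for the modelling assumptions and numerical
choices.
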