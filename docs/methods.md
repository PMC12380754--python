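# Methods

This note documents the models, parameter choices and numerical
decisions behind `pvkit`, and what the synthetic-data tests do and do
not demonstrate about real spontaneous-report data.

## Data model and ingestion

The unit of analysis is the *case*: one patient-event narrative that
may exist in several versions (follow-up submissions). The FAERS-style
ASCII dialect joins `$`-delimited DEMO/DRUG/REAC/THER/OUTC tables on
the report identifier; the generic CSV dialect outer-joins one CSV per
table on a `Report_ID` key, dropping exact-duplicate rows first.
Malformed rows (wrong field count) are skipped and counted, never
fatal; a missing mandatory table (DEMO/DRUG/REAC) is an error naming
the table.

**Deduplication** keeps, per case identifier, the version with the
latest receipt date, breaking ties by the numerically larger report
identifier. This is the published FDA guidance reading of
"deduplication"; both the rule and the removal count are logged. The
operation is idempotent.

**Primary-suspect restriction.** Only cases with at least one drug
entry whose verbatim name contains a target name (case-insensitive
substring — no RxNorm normalisation, matching how such queries are run
in practice) *and* whose role code is primary suspect (`PS`/`1`;
configurable for dialects that use e.g. "suspected drug") are analysed
as target-drug reports. Sensitivity corrections for concomitant
medication are out of scope; the PS restriction is the only
confounding control implemented.

**Units and codes.** Ages are converted to years from FAERS unit codes
(YR×1, DEC×10, MON÷12, WK÷52, DY÷365.25; HR and unknown codes become
unknown), weights to kg (KG, LBS). Sex codes normalise to
female/male/unknown. PT lists are uppercased and deduplicated per
report. Each PT maps to exactly one SOC through a user-supplied
2-column term map (primary-SOC convention); unmapped PTs are annotated
`UNMAPPED` and counted rather than dropped.

**Partial dates.** FAERS numeric dates may be year- or year-month-only.
They parse into a partial-date value usable for year-level filtering
but flagged incomplete for day-resolution arithmetic. A present but
invalid value (month 13, Feb 30, non-numeric) is kept distinct from an
absent one so exclusion logs can separate `unparseable` from
`incomplete_date`.

**Summary percentages** use the tally total of each characteristic as
denominator. For single-valued characteristics this equals the report
count; for multi-valued ones (e.g. outcome lists in some dialects) the
tally exceeds the report count, and the percentages are intentionally
of the tally — this is how published summary tables in this field are
constructed, and it is what makes them reproducible from their own
printed counts. Age bands default to <18 / 18–65 / >65 and are
configurable (e.g. the <15 / 15–65 / >65 variant used by Japanese
extracts).

## Contingency tables

The counting unit is the report: a report contributes at most once per
event label and once to the drug margin, so a+b+c+d = N for every
label and the margins reconcile with the per-label report counts.
Pair-level counting (each report×label pair) is available as an option
for comparability with sources that count "cases" per PT, with the
caveat that margins then count pairs. The comparator is the full
database view (all other drugs); restricted comparators can be
expressed by subsetting the report list before table construction.
Only labels with a ≥ 1 produce tables.

## Disproportionality statistics

- **ROR** with the Wald log-scale CI (Rothman); **PRR** with the
  Pearson χ²₁ statistic (Evans' convention; Yates correction off by
  default to match the PRR≥2 & χ²≥4 threshold family, available by
  flag). Zero-cell policy: Haldane–Anscombe +0.5 on all four cells,
  applied only when some cell is zero and only to the ratio estimates;
  χ² always uses raw counts; with the correction disabled a zero cell
  yields NaN flags, not exceptions.
- **BCPNN** in the Bate-1998 closed form with prior constants
  α₁=β₁=γ₁₁=1, α=β=2 (exposed in a config object). The priors
  guarantee finiteness on any table, including zero cells.
- **MGPS.** Counts are modelled a ~ Poisson(λE) with a two-component
  gamma prior on λ; the marginal is a two-component negative-binomial
  mixture whose parameters (α₁,β₁,α₂,β₂,w) are fitted by maximum
  likelihood over all labels. Optimisation: L-BFGS-B on
  log/logit-transformed parameters (box ±10 in log space) from
  DuMouchel's published start (0.2, 0.1, 2, 4, 1/3), plus a
  deterministic multi-start set — the surface has a null-dominated
  basin (a near-degenerate component at λ≈1 carrying most weight plus
  a diffuse signal component) that the single published start can
  miss when few labels carry signal — followed by a bounded
  Nelder–Mead polish. Failure to reach the starting likelihood raises
  an error carrying the best parameters found. At least ~20 labels
  are recommended for a meaningful fit.
- **EBGM** uses the digamma closed form for E[ln λ | a] under the
  posterior gamma mixture; **EBGM05** is found by Brent root-finding
  on the monotone mixture CDF with brackets from the component
  quantiles (expanded geometrically if needed), exact to ~1e-12 rather
  than a component-quantile approximation — exactness at this scale is
  cheap. Negative-binomial log-pmfs use `log1p` forms so that
  near-degenerate components (β ≫ E) do not lose the posterior weights
  to cancellation.
- **Bonferroni** adjustment applies to the χ² p-values; the family
  size defaults to the number of labels tested at that level in that
  database and is recorded with the results.

Note on interpretation: where a single "modified relative risk" summary
is wanted, the shrunken EBGM is the statistic of record here, being the
empirical-Bayes estimate of the relative reporting rate.

## Screening

Per-algorithm positivity at the standard published thresholds
(a≥3 & ROR CI low>1; PRR≥2 & χ²≥4 & a≥3; IC025>0; EBGM05≥2), all
configurable. Consensus: at PT level a label is significant only when
all four algorithms flag it, optionally gated on the
Bonferroni-adjusted p (<0.05); at SOC level ≥1 flag makes a label
positive and all four make it significant, with no Bonferroni gate
(the adjustment is a PT-level device here). Manual curation of
indication/pathology-driven signals is made explicit and reproducible
as a case-insensitive glob blocklist with reason tags; exclusions mark
rows, never delete them. Cross-database overlap is reported as the
full Venn decomposition: for every nonempty subset of databases, the
labels exclusive to exactly that subset; region sizes sum to the union
size by construction.

## Time to onset

Onset is event date minus the earliest therapy start among matching PS
drug entries, in calendar days. Same-day onsets (0 days) are retained.
Exclusions carry reasons (`incomplete_date`, `event_before_start`,
`unparseable`) and satisfy valid + excluded = input.

Numerical choices: quantiles use linear interpolation (type 7),
documented because published summaries rarely state their method;
binning uses a 30-day "month" ([0,30], (30,60], …; configurable);
zero-day onsets are replaced by 0.5 day *only inside the Weibull
likelihood* (support t > 0) so integer-day summaries are unaffected.

The Weibull MLE runs Newton iteration on the profile score in the
shape (the scale has a closed form given the shape), started at the
moment-style value 1.2/sd(ln t), with step-halving if an iterate goes
nonpositive; non-convergence raises with the iteration trace. CIs are
Wald intervals from the observed information on the (ln shape,
ln scale) scale, computed by central differences; the Wald-on-log
choice is made explicit since a likelihood-ratio interval would also
be defensible. Hazard-pattern classification follows the CI: early
failure iff the shape CI upper bound < 1, wear-out iff the lower
bound > 1, else random. Fewer than 10 values or an all-equal sample is
an error.

Kruskal–Wallis (tie-corrected, df = k−1) compares onset across SOCs; a
report with PTs in k SOCs contributes its onset to each of the k
groups, matching how per-SOC onset boxplots are built. An all-identical
pooled sample is the defined degenerate case H=0, p=1. The
Kaplan–Meier cumulative incidence (1 − product-limit survival) is kept
despite the absence of censoring in this design — it then equals the
empirical CDF — and is implemented with censoring support for reuse.

## Network pharmacology

All inputs are user-supplied plain text (gene lists, scored 2-column
tables, 3-column edge lists, GMT annotation sets); no remote database
is ever queried, so results are exactly reproducible from the input
snapshot. Scored target/disease exports are trimmed by a generic
threshold filter (inclusive ≥ by default, strict > available) before
intersection. The Venn percentage of an intersection is taken of the
union of the two sets. PPI edges are kept at score ≥ cutoff
(inclusive, matching "cutoff of 0.7" conventions); self-loops are
dropped and duplicate edges keep the larger score. Hub ranking uses
unweighted Brandes betweenness (normalized by (n−1)(n−2)/2 for
undirected graphs; ranking is normalisation-invariant within one
graph), ties broken alphabetically. Over-representation is the
upper-tail hypergeometric P(X ≥ overlap) with the annotation set
intersected with the universe first, zero-overlap sets reported at
p = 1 by convention, and Benjamini–Hochberg adjustment across all
tested sets.

## The synthetic cohort generator

The generator emulates the *statistical regime* of a spontaneous
reporting system, not any real database:

- One drug per report, drawn uniformly; role always PS. This mirrors a
  primary-suspect-restricted analysis; polypharmacy, indication
  channeling and notoriety bias are deliberately not modelled.
- Background event probabilities are a single symmetric Dirichlet(1)
  draw per configuration, so event margins vary realistically (pure
  uniform margins would make the χ² landscape degenerate across
  pairs); the draw is recorded in the cohort truth.
- Signal planting multiplies the event probability *conditional on the
  drug* by the relative-risk factor and renormalises the row, so the
  realised marginal relative risk sits slightly below the multiplier;
  recovery tolerances account for this. Events per report (1–3 by
  default) are sampled without replacement via Gumbel top-k
  perturbation, which needs no explicit renormalisation.
- Onsets are Weibull(shape 0.8, scale 10 days) by default — median
  ≈ 6 days with a decreasing hazard, the early-onset regime typical of
  anti-infective ADEs; therapy start dates are uniform over 2004–2023,
  receipt dates lag events by 2–180 days.
- Duplicates: a configurable fraction of cases (10% default) gain 1–2
  extra versions with the same case id, strictly later receipt dates,
  numerically larger report ids and possibly modified reaction lists —
  exactly the structure the dedup rule must undo; truth keeps the
  original case count.
- Date corruption: a configurable fraction of reports (20% default)
  get a truncated, missing or inverted date; every corruption kind
  makes the report a reasoned TTO exclusion, and the affected ids and
  kinds are recorded in truth.
- Demographic missingness defaults (sex 12%, age 20%, weight 70%,
  country 5%) reflect the heavy incompleteness of real extracts,
  weight most of all.
- Determinism: all randomness flows through per-stage
  `numpy.random.default_rng` streams derived from the configuration
  seed; identical configuration and seed give byte-identical output
  files.

What passing tests on this generator shows: the pipeline's
*mechanics* — counting, deduplication, exclusion accounting, the
statistics and their thresholds — behave correctly, with calibrated
false-positive rates under a true null and reliable recovery of strong
planted signals. What it does not show: robustness to the biases of
real spontaneous reports (underreporting, stimulated reporting,
multi-drug confounding, terminology drift), none of which are
simulated.

## Problem sizes used in the checks

The acceptance checks run at sizes chosen to make their statistical
claims meaningful while staying desk-scale: 20 null databases of
50,000 reports (consensus false-positive rate, bounded at 1%; IC025>0
rate, bounded at 5%), 20 replicates of a planted relative-risk-10 pair
in 20,000-report databases (recovery ≥ 95%), 100 Weibull replicates at
n = 657 with shape 0.8 and scale 10 (mean absolute relative shape
error < 5%, CI coverage near nominal), 100 random tables per
statistic/oracle comparison, and exhaustive enumeration oracles for
betweenness (10-node graphs) and the hypergeometric tail (20-gene
universe).

## Known limitations

- The MGPS fit is unstratified (no age/sex/year strata in E) and the
  contingency module builds no stratified tables.
- Drug-name matching is verbatim substring; misspellings and salts
  that do not contain a target name are missed.
- The Weibull CIs are Wald-based; for very small n (near the 10-value
  floor) likelihood-ratio intervals would be preferable.
- The generic CSV dialect treats the report identifier as the case
  identifier (no version structure); exact-duplicate rows are the only
  duplicate class it models.
- Country codes and indication vocabularies are passed through
  verbatim; no normalisation is attempted.
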