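# Methods

## Data model and de-duplication

A report is the unit of counting throughout: one `ReportRecord` per DEMO
row, joined to its DRUG/REAC/INDI/OUTC rows by `primaryid`, with events
stored as a set (a PT reported twice in one report counts once).  FAERS
re-publishes updated versions of a case under the same CASEID with a new
PRIMARYID; de-duplication keeps, per CASEID, the version with the latest
FDA_DT and, at equal dates, the numerically larger PRIMARYID.  A missing
FDA_DT sorts earliest, so a dated version always beats an undated one —
preferring more complete records.  PRIMARYID comparison is numeric when
both values parse as integers (FAERS primaryids are numeric strings) and
lexicographic otherwise.  The operation is idempotent and invariant to
input row order; survivors are emitted in (caseid, primaryid) order so
downstream artifacts are byte-reproducible.

Unit normalization is total: age codes DEC (×10), YR, MON (÷12),
WK (÷52.1775), DY (÷365.25), HR (÷8766) and weight codes KG, LBS
(×0.453592), GMS (÷1000) map to years/kilograms; unknown codes,
unparseable values, and values outside plausibility windows (age 0–150 y,
weight 0–650 kg) become missing, never exceptions.  Files decode as UTF-8
with a Latin-1 fallback; rows with the wrong field count are rejected and
counted in provenance (real quarters contain stray delimiters), and
provenance must reconcile (accepted + rejected = parsed).

## Cohorts

Drug matching is exact on normalized names (uppercased, whitespace
collapsed, trailing dosage/salt tokens stripped) against a synonym
dictionary holding generic and brand names for the 14-agent panel; both
the verbatim `drugname` (where brands appear) and `prod_ai` (actives) are
checked.  Only primary-suspect (PS) mentions enter a cohort — the
specificity-maximizing convention.  Indication filtering is available and
links a qualifying term to the matched drug's `drug_seq` (with a
report-level fallback flag); the pipeline default leaves it off so that
cohort counts match the synthetic generator's exposure accounting exactly,
and because the generator assigns qualifying indications only
probabilistically, mimicking real-world incompleteness.  No fuzzy matching
and no imputation of missing demographics: descriptive tables count
"missing" as its own category, and `missingness_profile` reports per-field
missing fractions instead of imputing.

## Disproportionality

The 2×2 background for (c, d) is the entire de-duplicated corpus minus the
cohort — not the other panel drugs only — with the expected count
E = (a+b)(a+c)/N.  No stratification of E is applied by default.
Statistics undefined on sparse tables (zero cells/margins for PRR and ROR)
are carried as NaN with their criterion flag set false, so pipelines never
crash on rare PTs.

* χ² uses the Yates continuity correction by default (the dominant
  convention in this literature), with Pearson available; the Yates
  numerator base is floored at zero.
* The BCPNN information component uses the gamma-posterior
  observed/expected formulation: λ | a ~ Gamma(a + ½, E + ½),
  IC = log₂[(a+½)/(E+½)], and IC₀₂₅ the exact posterior 2.5th percentile
  (log₂ scale).  A "two-sigma" normal-approximation variant
  (IC − 2·SD[log₂ λ]) is available by flag for compatibility with older
  implementations.
* MGPS: the marginal likelihood of the counts is a two-component negative
  binomial mixture.  Hyperparameters are fitted in unconstrained space
  (log shapes/rates, logit weight) by Nelder-Mead, multi-started from the
  conventional point (0.2, 0.1, 2.0, 4.0, ⅓) plus seeded random
  perturbations.  The likelihood can have a long, nearly flat ridge — one
  component drifting toward a point mass near λ = 1 when the bulk of pairs
  is null — so a start that exhausts its iteration budget is polished by a
  restarted simplex and accepted as stationary when the polish improves
  the objective by less than 1e-7 relative; genuinely non-convergent fits
  raise an error carrying best-so-far diagnostics.  The default fitting
  scope is pairs with a ≥ 1 (with a flag to include the zero-count grid,
  which is the right choice when the zeros are real observations, e.g. in
  simulation studies).  Scoring uses the exact posterior mixture:
  EBGM = exp(E[ln λ]) via digamma, and EB05 by bracketed root-finding on
  the mixture CDF to absolute tolerance 1e-8 (the root is bracketed
  between the component 5th-percentiles, widened to absorb endpoint
  rounding).
* Thresholds: PRR ≥ 2 ∧ χ² ≥ 4 ∧ a ≥ 3; ROR₀₂₅ > 1 (strict); IC₀₂₅ > 0
  (strict); EB05 ≥ 2.  The report-count floor lives inside the PRR flag;
  since the key call is the conjunction of all four flags, it gates the
  key signal either way.  No further multiplicity adjustment is applied —
  the concordance requirement itself is the false-positive control.

Ranking is deterministic: descending by the chosen field (report count a,
or EBGM), ties broken by the other field descending, then PT
lexicographically.

## Atlas and shared-PT analysis

MedDRA content is licensed, so the PT→SOC mapping is a user-supplied
two-column file; MedDRA's multiaxiality is collapsed to one primary SOC
per PT so that per-drug PT counts are conserved under the SOC grouping
(the conservation is a tested invariant).  Unmapped PTs fall under an
`UNMAPPED` sentinel rather than being dropped.  The marker–organ
concordance flag — joint enrichment of the Investigations SOC and a
configured organ SOC — uses a minimum-PT-count rule (default 2 in each);
this quantitative criterion is a package convention, since "concurrent
enrichment" has no canonical numeric definition.

## Similarity network and MDS

Jaccard similarity is computed over key-signal PT sets; J = 0 by
convention (with a warning) when both sets are empty.  The backbone
threshold is the linear-interpolation ("type 7") quantile of the
n(n−1)/2 off-diagonal similarities, and ties at the threshold are
retained ("at or above"), so the surviving fraction can exceed the nominal
20% — including the degenerate case where many similarities are exactly
zero and a low percentile retains every edge.  Drugs with empty signal
sets remain as isolated nodes so the node panel is stable.  Heatmap leaf
order comes from average-linkage clustering of 1 − J with labels
pre-sorted, making the order invariant to input permutation.  MDS is
classical Torgerson: B = −½·C·D²·C, eigendecomposition, top-2 nonnegative
eigenpairs; eigenvalues within round-off of zero are clamped (null-space
noise must not leak into coordinates), negative-eigenvalue mass is
reported, and axis signs are fixed by making the largest-magnitude
coordinate on each axis positive, so embeddings are snapshot-stable.
Classical MDS is implemented directly (rather than delegated to a SMACOF
optimizer) because the principal-coordinate construction, the eigenvalue
report and the sign convention are part of the contract.

## Synthetic corpus generator

The generator emulates the seven-quarterly-table FAERS dialect with a
known signal structure: each report draws one primary-suspect drug by
exposure probability (panel agent or one of 20 background drugs), then
each PT independently with its background probability, multiplied by rho
(capped at 0.99, with a warning) for planted (drug, PT) pairs.  Events
are conditionally independent given the drug — the simplest structure
under which the 2×2 disproportionality model is well specified — so
recovery rates measured here should not be read as real-data operating
characteristics.  Duplicates mimic FAERS versioning (same CASEID, new
larger PRIMARYID, later FDA_DT, identical content) rather than row copies,
so the real de-duplication rule is exercised.  Demographics, outcomes,
reporter fields and per-field missingness are configurable; a mock PT→SOC
map and a ground-truth table (planted triples with expected and realized
counts) are emitted alongside.

Defaults mirror the study design: 14 drugs across 5 target classes, each
with exposure probability 0.018 (≈900 exposed reports per drug at the
default 50 000-report corpus — a mid-sized FAERS cohort); 200 PTs with
background probabilities of 0.4–1.5%, giving ≈2 events per report; per
class a shared planted block of 6 PTs and per drug a disjoint unique
block of 4 PTs, all at rho = 5 on a 1% background (expected a ≈ 45,
comfortably above the detectability floor of the EB05 ≥ 2 criterion);
duplicate fraction 5%; missingness 5–30% by field, heaviest for weight,
matching the pattern of real FAERS demographics.  Sensitivity is scored
over planted pairs with expected a ≥ 10 and rho ≥ 5; the false-positive
proportion over all non-planted (panel drug × vocabulary PT) pairs.

What the generator does **not** model: reporting dynamics over time,
drug–drug interactions, PT–PT dependence, notoriety bias, or duplicated
content with conflicting field values.  Passing recovery tests therefore
demonstrates correctness of the machinery, not field performance.

## Pipeline and reproducibility

`run_all` executes ingest → dedup → cohorts → signals → atlas →
shared-PT → similarity/backbone/MDS, writing every interface table, a
resolved config, a run log with per-stage drop accounting, and a
`manifest.json` (seed, counts per stage, fitted prior, backbone edge
counts).  All randomness flows from the single config seed; reruns are
byte-identical.  Stage functions are importable individually, and the
normalized store round-trips through `write_store`/`load_store`, which is
how partial reruns are done; the CLI intentionally exposes only
`simulate`, `run` and `evaluate`.

Problem sizes used by the test suite: the end-to-end fixture runs the
full default 50 000-report corpus once per session; unit tests use
1 000–8 000-report corpora, 1 000-table oracle sweeps and 5 000-pair MGPS
recovery simulations — sizes at which every stochastic check is stable
across seeds while the whole suite stays fast.

## Known limitations

* Exact name matching only; misspelled verbatims in real data are missed.
* The background universe is whatever was ingested; with a single quarter
  loaded, (c, d) reflect that quarter only.
* The MGPS fitting scope (a ≥ 1 by default) follows one of the two
  conventions in the literature; with heavy truncation the implied prior
  is biased relative to a zero-inclusive fit.
* No multiple imputation: missingness is profiled, not filled.
* The pre-2012 LAERS layout is rejected with a documented error rather
  than parsed.
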