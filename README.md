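# faerspv

Pharmacovigilance signal detection on FAERS-shaped spontaneous-report data,
built for the targeted-therapy setting in non-small cell lung cancer
(NSCLC): 14 FDA-approved agents across five target classes (EGFR, ALK,
ROS1, RET, KRAS-G12C).  The package takes the FDA Adverse Event Reporting
System's quarterly `$`-delimited ASCII tables (or a ground-truthed
synthetic stand-in it generates itself), and produces per-drug adverse-event
signal tables, a drug–SOC–PT atlas, and a cross-drug similarity network.

## Who this is for

Pharmacoepidemiologists and biostatisticians who want a tested, scriptable
implementation of the standard disproportionality toolkit — with the case
de-duplication, primary-suspect restriction and name-matching plumbing that
real FAERS analyses require — plus a synthetic corpus generator that makes
every stage verifiable against known ground truth.

## The statistics

For each drug–event pair, reports are cross-classified into a 2×2 table
(a = drug & event, b = drug only, c = event only, d = neither), with
N = a+b+c+d and expected count E = (a+b)(a+c)/N.  Four measures are
computed:

* **PRR** = [a/(a+b)] / [c/(c+d)], with a χ² statistic (Yates-corrected by
  default): signal when PRR ≥ 2, χ² ≥ 4 and a ≥ 3.
* **ROR** = ad/bc with a Wald 95% CI on the log scale: signal when
  ROR₀₂₅ > 1.
* **BCPNN IC** = log₂ of the shrunk observed/expected ratio; the rate
  ratio has posterior Gamma(a + ½, E + ½) and IC₀₂₅ is the exact 2.5th
  posterior percentile: signal when IC₀₂₅ > 0.
* **MGPS EBGM** — DuMouchel's gamma–Poisson shrinker: a ~ Poisson(λE) with
  a two-component gamma mixture prior on λ fitted by maximum marginal
  likelihood across all pairs; EBGM is the posterior geometric mean and
  EB05 the posterior 5th percentile: signal when EB05 ≥ 2.

A pair is a **key signal** only when all four criteria hold simultaneously;
this concordance rule is the false-positive control.  Key-signal PT sets
then drive the downstream structure: PT→SOC atlases, shared-PT counts,
pairwise Jaccard similarity J = |∩|/|∪| between drugs, an 80th-percentile
network backbone (70th/90th as sensitivity), and a classical (Torgerson)
MDS embedding of the Jaccard distance 1 − J.

## Worked example

One sparse drug–event table, all four methods (`examples/02_disproportionality.py`):

```text
table a=5 b=15 c=5 d=75  N=100  E=2.0
PRR  = 4.0000   chi2 = 4.3403
ROR  = 5.0000   95% CI (1.2860, 19.4402)
IC   = 1.1375   IC025 = -0.3900
EBGM = 1.5989   EB05 = 0.6436
flags: PRR True, ROR True, IC False, EBGM False -> key = False
```

The raw disproportion is 2.5-fold (a/E), and both frequentist criteria
pass — but with only five reports the Bayesian shrinkage pulls the interval
bounds below their thresholds, so the pair is not called.  That asymmetry
at small counts is precisely why the four-way concordance rule suppresses
false positives.

The full pipeline on a synthetic corpus with planted signals
(`examples/03_full_pipeline.py`, 20 000 reports):

```text
cohort sizes: 331-395 reports/drug
key-signal set sizes: 7-10 PTs/drug
fitted MGPS prior mixture weight p = 0.062
planted-pair sensitivity: 0.821 (115/140)
null false-positive proportion: 0.0000 (0/2660)
PTs shared by all drugs: none
```

Each drug carries 10 planted PTs (6 shared within its target class + 4
drug-unique) at five-fold elevated reporting rates; most are recovered
while no null pair is flagged.  At the default 50 000-report corpus the
sensitivity reaches 1.0.  See `examples/04_similarity_network.py` for the
Jaccard/backbone/MDS stage, where target classes emerge as network modules.

A thin CLI wraps the same pipeline:

```bash
faerspv simulate --n-reports 20000 --seed 7 --out corpus/
faerspv run --inputs corpus/DEMO25Q2.txt --inputs corpus/DRUG25Q2.txt ... --out run/
faerspv evaluate run/
```

## Real FAERS data

Point `faerspv run --inputs ...` (or `RunConfig.input_paths`) at the
quarterly ASCII files from the FDA's FAERS download site.  You must supply
your own MedDRA PT→SOC mapping file (MedDRA is licensed and not bundled);
drug synonyms and NSCLC indication terms ship with editable defaults.
Note that published headline counts from full 2004–2025 snapshots depend
on that external, version-dependent download and are not reproduced here.
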