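"""Study-drug cohorts: name matching, primary-suspect restriction, descriptives.

A cohort is the set of de-duplicated reports in which the study drug is the
primary suspect (PS), optionally further restricted to reports carrying a
qualifying indication term on that drug's sequence.  The default dictionary
covers the 14 targeted agents used in NSCLC across five target classes
(EGFR, ALK, ROS1, RET, KRAS-G12C), with generic and brand synonyms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .faers_io import ReportRecord, ReportStore

__all__ = [
    "DrugDictionary",
    "IndicationTermSet",
    "Cohort",
    "normalize_name",
    "match_drug",
    "build_cohort",
    "descriptive_summary",
    "yearly_counts",
    "missingness_profile",
    "default_drug_dictionary",
    "default_indication_terms",
]

#: dosage/salt suffix tokens stripped during name normalization
DEFAULT_STOP_TOKENS = frozenset({
    "MESYLATE", "MESILATE", "HYDROCHLORIDE", "HCL", "DIMALEATE", "MALEATE",
    "TABLETS", "TABLET", "CAPSULE", "CAPSULES", "MG", "ORAL",
})

_WS = re.compile(r"\s+")


def normalize_name(verbatim: str, stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS) -> str:
    """Uppercase, trim, collapse whitespace, drop trailing dosage/salt tokens."""
    tokens = _WS.sub(" ", (verbatim or "").strip().upper()).split(" ")
    while tokens and tokens[-1] in stop_tokens:
        tokens.pop()
    return " ".join(t for t in tokens if t)


# --- drug dictionary ------------------------------------------------------

_DEFAULT_PANEL: list[tuple[str, str, list[str]]] = [
    ("gefitinib", "EGFR", ["GEFITINIB", "IRESSA"]),
    ("erlotinib", "EGFR", ["ERLOTINIB", "TARCEVA"]),
    ("afatinib", "EGFR", ["AFATINIB", "GILOTRIF", "GIOTRIF"]),
    ("dacomitinib", "EGFR", ["DACOMITINIB", "VIZIMPRO"]),
    ("osimertinib", "EGFR", ["OSIMERTINIB", "TAGRISSO"]),
    ("crizotinib", "ALK", ["CRIZOTINIB", "XALKORI"]),
    ("ceritinib", "ALK", ["CERITINIB", "ZYKADIA"]),
    ("alectinib", "ALK", ["ALECTINIB", "ALECENSA"]),
    ("brigatinib", "ALK", ["BRIGATINIB", "ALUNBRIG"]),
    ("lorlatinib", "ALK", ["LORLATINIB", "LORBRENA", "LORVIQUA"]),
    ("repotrectinib", "ROS1", ["REPOTRECTINIB", "AUGTYRO"]),
    ("pralsetinib", "RET", ["PRALSETINIB", "GAVRETO"]),
    ("selpercatinib", "RET", ["SELPERCATINIB", "RETEVMO", "RETSEVMO"]),
    ("adagrasib", "KRAS-G12C", ["ADAGRASIB", "KRAZATI"]),
]


@dataclass
class DrugDictionary:
    """Canonical drug id -> synonyms (generic + brand) and target class."""

    entries: dict[str, list[str]]
    classes: dict[str, str]
    _lookup: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._lookup = {}
        for drug_id, synonyms in self.entries.items():
            if not synonyms:
                raise ValueError(f"drug {drug_id!r} has no synonyms")
            if drug_id not in self.classes:
                raise ValueError(f"drug {drug_id!r} has no target class")
            for syn in synonyms:
                norm = normalize_name(syn)
                other = self._lookup.get(norm)
                if other is not None and other != drug_id:
                    raise ValueError(
                        f"synonym {syn!r} maps to both {other!r} and {drug_id!r}")
                self._lookup[norm] = drug_id

    @property
    def drug_ids(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DrugDictionary":
        data = yaml.safe_load(Path(path).read_text())
        return cls(entries={d: list(v["synonyms"]) for d, v in data.items()},
                   classes={d: v["class"] for d, v in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        data = {d: {"class": self.classes[d], "synonyms": self.entries[d]}
                for d in self.entries}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_drug_dictionary() -> DrugDictionary:
    """The 14-agent NSCLC targeted-therapy panel with brand synonyms."""
    return DrugDictionary(
        entries={d: list(syn) for d, _, syn in _DEFAULT_PANEL},
        classes={d: cls for d, cls, _ in _DEFAULT_PANEL},
    )


def match_drug(verbatim: str, dictionary: DrugDictionary) -> str | None:
    """Exact match of the normalized verbatim name against normalized synonyms."""
    return dictionary._lookup.get(normalize_name(verbatim))


# --- indications ----------------------------------------------------------


@dataclass(frozen=True)
class IndicationTermSet:
    """Indication terms delimiting the study population (exact, normalized)."""

    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("indication term set is empty")
        object.__setattr__(self, "terms",
                           frozenset(normalize_name(t, frozenset()) for t in self.terms))

    def __contains__(self, term: str) -> bool:
        return normalize_name(term, frozenset()) in self.terms


def default_indication_terms() -> IndicationTermSet:
    """NSCLC indication terms; fully overrideable via config."""
    return IndicationTermSet(frozenset({
        "NON-SMALL CELL LUNG CANCER",
        "NON-SMALL CELL LUNG CANCER METASTATIC",
        "NON-SMALL CELL LUNG CANCER RECURRENT",
        "NON-SMALL CELL LUNG CANCER STAGE IV",
        "LUNG ADENOCARCINOMA",
        "LUNG SQUAMOUS CELL CARCINOMA",
        "ADENOCARCINOMA OF LUNG",
    }))


# --- cohort construction --------------------------------------------------


@dataclass
class Cohort:
    """Reports where ``drug_id`` is primary suspect (plus optional indication)."""

    drug_id: str
    reports: list[ReportRecord]

    def __len__(self) -> int:
        return len(self.reports)


def _ps_seqs(report: ReportRecord, drug_id: str, dictionary: DrugDictionary) -> list[int]:
    """drug_seq values where this report names drug_id as primary suspect.

    Both the verbatim drugname (brands) and prod_ai (actives) are checked.
    """
    seqs = []
    for mention in report.drugs:
        if mention.role != "PS":
            continue
        hit = match_drug(mention.verbatim_name, dictionary)
        if hit is None and mention.prod_ai:
            hit = match_drug(mention.prod_ai, dictionary)
        if hit == drug_id:
            seqs.append(mention.drug_seq)
    return seqs


def build_cohort(
    store: ReportStore,
    drug_id: str,
    dictionary: DrugDictionary,
    indications: IndicationTermSet | None = None,
    require_indication: bool = False,
    indication_linkage: str = "drug_seq",
) -> Cohort:
    """Select reports with the study drug as primary suspect.

    With ``require_indication``, a qualifying indication must attach to the
    matched drug's drug_seq (``indication_linkage="drug_seq"``) or anywhere
    on the report (``"report"`` fallback).
    """
    if drug_id not in dictionary.entries:
        raise KeyError(f"unknown drug id {drug_id!r}")
    if require_indication and indications is None:
        raise ValueError("require_indication=True needs an IndicationTermSet")
    selected = []
    for rec in store.reports:
        seqs = _ps_seqs(rec, drug_id, dictionary)
        if not seqs:
            continue
        if require_indication:
            assert indications is not None
            if indication_linkage == "drug_seq":
                ok = any(seq in seqs and term in indications
                         for seq, term in rec.indications)
            else:
                ok = any(term in indications for _, term in rec.indications)
            if not ok:
                continue
        selected.append(rec)
    return Cohort(drug_id=drug_id, reports=selected)


# --- descriptives ---------------------------------------------------------

AGE_BINS = [(-np.inf, 18.0, "<18"), (18.0, 65.0, "18-64.9"),
            (65.0, 85.0, "65-85"), (85.0, np.inf, ">85")]
WEIGHT_BINS = [(-np.inf, 50.0, "<50"), (50.0, 100.0, "50-100"),
               (100.0, np.inf, ">100")]
OUTCOME_LABELS = {"DE": "Death", "LT": "Life-threatening", "HO": "Hospitalization",
                  "DS": "Disability", "CA": "Congenital anomaly",
                  "RI": "Required intervention", "OT": "Other serious"}


def _bin_label(x: float, bins) -> str:
    for lo, hi, label in bins:
        # upper edge inclusive on the last bin; [lo, hi) otherwise
        if lo <= x < hi or (hi is np.inf and x >= lo):
            return label
    return "unbinned"


def descriptive_summary(cohort: Cohort) -> pd.DataFrame:
    """Counts/percentages by sex, reporter type, outcome, binned age/weight,
    plus mean/SD and median/IQR for age and weight.

    Multi-outcome reports count once per outcome category; missing values
    are a separate row, never imputed.  Returns a tidy frame with columns
    (section, category, count, percent, value).
    """
    n = len(cohort)
    rows: list[dict] = []

    def _counts(section: str, values: list[str]) -> None:
        vc = pd.Series(values, dtype=object).value_counts()
        for cat, cnt in vc.items():
            pct = 100.0 * cnt / n if n else np.nan
            rows.append({"section": section, "category": cat,
                         "count": int(cnt), "percent": pct, "value": np.nan})

    _counts("sex", [r.sex if r.sex in ("F", "M") else "missing"
                    for r in cohort.reports])
    _counts("reporter_type", [r.reporter_type for r in cohort.reports])

    outc = [OUTCOME_LABELS[c] for r in cohort.reports for c in sorted(r.outcomes)]
    vc = pd.Series(outc, dtype=object).value_counts()
    for cat, cnt in vc.items():
        rows.append({"section": "outcome", "category": cat, "count": int(cnt),
                     "percent": 100.0 * cnt / n if n else np.nan, "value": np.nan})

    for name, values, bins in (
        ("age_years", [r.age_years for r in cohort.reports], AGE_BINS),
        ("weight_kg", [r.weight_kg for r in cohort.reports], WEIGHT_BINS),
    ):
        present = np.array([v for v in values if v is not None], dtype=float)
        n_missing = sum(1 for v in values if v is None)
        _counts(f"{name}_bin",
                [_bin_label(v, bins) if v is not None else "missing" for v in values])
        stats = {
            "mean": present.mean() if present.size else np.nan,
            "sd": present.std(ddof=1) if present.size > 1 else np.nan,
            "median": float(np.median(present)) if present.size else np.nan,
            "q1": float(np.percentile(present, 25)) if present.size else np.nan,
            "q3": float(np.percentile(present, 75)) if present.size else np.nan,
        }
        for stat, value in stats.items():
            rows.append({"section": name, "category": stat, "count": np.nan,
                         "percent": np.nan, "value": value})
        rows.append({"section": name, "category": "missing", "count": n_missing,
                     "percent": 100.0 * n_missing / n if n else np.nan,
                     "value": np.nan})

    df = pd.DataFrame(rows, columns=["section", "category", "count", "percent", "value"])
    df.attrs["n"] = n
    df.attrs["empty_cohort"] = n == 0
    return df


def yearly_counts(cohort: Cohort) -> pd.Series:
    """Report counts by calendar year of FDA_DT; missing dates bucketed apart."""
    years = []
    for r in cohort.reports:
        if r.fda_dt and len(r.fda_dt) >= 4 and r.fda_dt[:4].isdigit():
            years.append(int(r.fda_dt[:4]))
        else:
            years.append(-1)
    s = pd.Series(years, dtype=int).value_counts().sort_index()
    s.index = [("missing" if y == -1 else y) for y in s.index]
    s.name = "reports"
    return s


def missingness_profile(cohort: Cohort) -> pd.Series:
    """Fraction of reports missing each baseline field, in [0, 1]."""
    n = len(cohort)
    fields = {
        "sex": lambda r: r.sex not in ("F", "M"),
        "age_years": lambda r: r.age_years is None,
        "weight_kg": lambda r: r.weight_kg is None,
        "reporter_country": lambda r: r.reporter_country is None,
        "reporter_type": lambda r: r.reporter_type == "missing",
        "fda_dt": lambda r: r.fda_dt is None,
    }
    if n == 0:
        s = pd.Series({k: np.nan for k in fields}, name="fraction_missing")
        s.attrs["empty_cohort"] = True
        return s
    s = pd.Series({k: sum(f(r) for r in cohort.reports) / n
                   for k, f in fields.items()}, name="fraction_missing")
    s.attrs["empty_cohort"] = False
    return s
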