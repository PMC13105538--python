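"""Reading, validating and de-duplicating FAERS-dialect quarterly tables.

FAERS distributes seven ``$``-delimited ASCII tables per quarter (DEMO, DRUG,
REAC, OUTC, RPSR, THER, INDI).  This module parses them into a normalized
in-memory :class:`ReportStore` of one :class:`ReportRecord` per report,
normalizes age/weight units, and applies the FDA case de-duplication rule:
one surviving report per CASEID, keeping the most recent FDA_DT and, at equal
dates, the numerically larger PRIMARYID.
"""

from __future__ import annotations

import functools
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "DrugMention",
    "ReportRecord",
    "ReportStore",
    "SchemaError",
    "InputError",
    "read_faers_tables",
    "deduplicate",
    "write_store",
    "load_store",
]


class SchemaError(ValueError):
    """A required column or table is absent from the input."""


class InputError(ValueError):
    """Input present but unusable (e.g. empty DEMO table)."""


# --- unit normalization tables -------------------------------------------

#: multiplicative factor taking AGE in the coded unit to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: multiplicative factor taking WT in the coded unit to kilograms
WEIGHT_UNIT_TO_KG = {
    "KG": 1.0,
    "KGS": 1.0,
    "LBS": 0.453592,
    "IB": 0.453592,
    "GMS": 0.001,
}

AGE_RANGE = (0.0, 150.0)
WEIGHT_RANGE = (0.0, 650.0)  # exclusive lower bound

REPORTER_TYPE_CODES = {
    "CN": "consumer",
    "HP": "health-professional",
    "PH": "pharmacist",
    "MD": "physician",
    "OT": "other",
    "LW": "other",
    "RN": "health-professional",
}

OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

REQUIRED_COLUMNS = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "sex", "age", "age_cod",
        "wt", "wt_cod", "occp_cod", "reporter_country",
    ],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "pt"],
    "INDI": ["primaryid", "indi_drug_seq", "indi_pt"],
    "OUTC": ["primaryid", "outc_cod"],
    "THER": ["primaryid"],
    "RPSR": ["primaryid"],
}

_TABLE_RE = re.compile(r"^(DEMO|DRUG|REAC|INDI|OUTC|THER|RPSR)", re.IGNORECASE)


def normalize_age_years(value: str | float | None, code: str | None) -> float | None:
    """Convert an (AGE, AGE_COD) pair to years; unparseable input -> None.

    Total: every (value, code) pair maps to a number or to None, never an
    exception.  Values outside [0, 150] years are treated as recording
    errors and returned as None.
    """
    factor = AGE_UNIT_TO_YEARS.get((code or "").strip().upper())
    if factor is None:
        return None
    try:
        years = float(value) * factor
    except (TypeError, ValueError):
        return None
    if not (AGE_RANGE[0] <= years <= AGE_RANGE[1]):
        return None
    return years


def normalize_weight_kg(value: str | float | None, code: str | None) -> float | None:
    """Convert a (WT, WT_COD) pair to kilograms; unparseable input -> None."""
    factor = WEIGHT_UNIT_TO_KG.get((code or "").strip().upper())
    if factor is None:
        return None
    try:
        kg = float(value) * factor
    except (TypeError, ValueError):
        return None
    if not (WEIGHT_RANGE[0] < kg < WEIGHT_RANGE[1]):
        return None
    return kg


@dataclass(frozen=True)
class DrugMention:
    """One DRUG-table row attached to a report."""

    verbatim_name: str
    role: str  # PS, SS, C or I
    drug_seq: int
    prod_ai: str | None = None
    matched_drug_id: str | None = None


@dataclass
class ReportRecord:
    """One spontaneous report after joining the seven FAERS tables."""

    primaryid: str
    caseid: str
    fda_dt: str | None  # YYYYMMDD
    sex: str  # 'F', 'M' or 'unknown'
    age_years: float | None
    weight_kg: float | None
    reporter_country: str | None
    reporter_type: str  # consumer/health-professional/pharmacist/physician/other/missing
    outcomes: frozenset[str]
    drugs: list[DrugMention]
    events: frozenset[str]
    indications: list[tuple[int, str]]  # (drug_seq, indication term)


@dataclass
class ReportStore:
    """A collection of reports plus parsing provenance.

    ``provenance`` entries record, per input file, the number of data rows
    parsed, accepted and rejected; accepted + rejected = parsed always holds.
    """

    reports: list[ReportRecord] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)
    deduplicated: bool = False

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[ReportRecord]:
        return iter(self.reports)

    def caseids(self) -> list[str]:
        return [r.caseid for r in self.reports]

    def check_provenance(self) -> None:
        for entry in self.provenance:
            if entry["accepted"] + entry["rejected"] != entry["parsed"]:
                raise AssertionError(f"provenance does not reconcile: {entry}")


# --- parsing --------------------------------------------------------------


def _read_dollar_table(path: Path) -> tuple[list[str], list[list[str]], int]:
    """Read one ``$``-delimited table; returns (header, rows, n_rejected).

    Decodes UTF-8 with a Latin-1 fallback; rows whose field count differs
    from the header are rejected (stray delimiters occur in real quarters).
    """
    raw = Path(path).read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("latin-1")
    lines = text.splitlines()
    if not lines:
        return [], [], 0
    header = [h.strip().lower() for h in lines[0].split("$")]
    n = len(header)
    rows: list[list[str]] = []
    rejected = 0
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("$")
        if len(fields) != n:
            rejected += 1
            continue
        rows.append(fields)
    return header, rows, rejected


def _table_kind(path: Path) -> str | None:
    m = _TABLE_RE.match(Path(path).name)
    return m.group(1).upper() if m else None


def _quarter_of(path: Path) -> str:
    m = re.search(r"(\d{2}Q\d)", Path(path).name, re.IGNORECASE)
    return m.group(1).upper() if m else "unknown"


def _check_columns(kind: str, header: Sequence[str], path: Path) -> dict[str, int]:
    idx = {name: i for i, name in enumerate(header)}
    for col in REQUIRED_COLUMNS[kind]:
        if col not in idx:
            raise SchemaError(f"{path}: required column {col!r} missing from {kind} table")
    return idx


def _blank_to_none(value: str) -> str | None:
    v = value.strip()
    return v if v else None


def read_faers_tables(paths: Iterable[str | Path], schema_version: str = "faers") -> ReportStore:
    """Parse FAERS quarterly ASCII tables into a :class:`ReportStore`.

    Parameters
    ----------
    paths
        Files named ``DEMOyyQq.txt`` etc.; the table kind is inferred from
        the filename prefix.  DEMO must be present.
    schema_version
        Only the post-2012 ``"faers"`` dialect is supported; the legacy
        LAERS layout raises a documented error.

    One ReportRecord is produced per accepted DEMO row; DRUG/REAC/INDI/OUTC
    rows are joined by primaryid.  Join orphans (child rows whose primaryid
    has no DEMO row) are counted in provenance and dropped.
    """
    if schema_version != "faers":
        raise SchemaError(
            f"unsupported schema version {schema_version!r}: only the post-2012 "
            "FAERS dialect is handled"
        )
    by_kind: dict[str, list[Path]] = {}
    for p in paths:
        kind = _table_kind(Path(p))
        if kind is not None:
            by_kind.setdefault(kind, []).append(Path(p))
    if "DEMO" not in by_kind:
        raise SchemaError("no DEMO table among the input paths")

    store = ReportStore()
    records: dict[str, ReportRecord] = {}
    order: list[str] = []

    for path in by_kind["DEMO"]:
        header, rows, rejected = _read_dollar_table(path)
        idx = _check_columns("DEMO", header, path)
        store.provenance.append({
            "file": str(path), "table": "DEMO", "quarter": _quarter_of(path),
            "parsed": len(rows) + rejected, "accepted": len(rows), "rejected": rejected,
        })
        for row in rows:
            pid = row[idx["primaryid"]].strip()
            if not pid:
                continue
            sex_raw = (row[idx["sex"]] or "").strip().upper()
            occp = (row[idx["occp_cod"]] or "").strip().upper()
            rec = ReportRecord(
                primaryid=pid,
                caseid=row[idx["caseid"]].strip(),
                fda_dt=_blank_to_none(row[idx["fda_dt"]]),
                sex=sex_raw if sex_raw in ("F", "M") else "unknown",
                age_years=normalize_age_years(row[idx["age"]], row[idx["age_cod"]]),
                weight_kg=normalize_weight_kg(row[idx["wt"]], row[idx["wt_cod"]]),
                reporter_country=_blank_to_none(row[idx["reporter_country"]]),
                reporter_type=REPORTER_TYPE_CODES.get(occp, "missing"),
                outcomes=frozenset(),
                drugs=[],
                events=frozenset(),
                indications=[],
            )
            if pid not in records:
                order.append(pid)
            records[pid] = rec
    if not records:
        raise InputError("DEMO table(s) contain no usable rows")

    def _join(kind: str, consume) -> None:
        for path in by_kind.get(kind, []):
            header, rows, rejected = _read_dollar_table(path)
            idx = _check_columns(kind, header, path)
            orphans = 0
            for row in rows:
                pid = row[idx["primaryid"]].strip()
                rec = records.get(pid)
                if rec is None:
                    orphans += 1
                    continue
                consume(rec, row, idx)
            store.provenance.append({
                "file": str(path), "table": kind, "quarter": _quarter_of(path),
                "parsed": len(rows) + rejected, "accepted": len(rows),
                "rejected": rejected, "orphans": orphans,
            })

    def _add_drug(rec: ReportRecord, row: list[str], idx: dict[str, int]) -> None:
        role = (row[idx["role_cod"]] or "").strip().upper()
        try:
            seq = int(float(row[idx["drug_seq"]]))
        except (TypeError, ValueError):
            seq = len(rec.drugs) + 1
        rec.drugs.append(DrugMention(
            verbatim_name=row[idx["drugname"]].strip(),
            role=role if role in ROLE_CODES else "C",
            drug_seq=seq,
            prod_ai=_blank_to_none(row[idx["prod_ai"]]),
        ))

    def _add_reac(rec: ReportRecord, row: list[str], idx: dict[str, int]) -> None:
        pt = row[idx["pt"]].strip()
        if pt:
            rec.events = rec.events | {pt}

    def _add_indi(rec: ReportRecord, row: list[str], idx: dict[str, int]) -> None:
        term = row[idx["indi_pt"]].strip()
        if not term:
            return
        try:
            seq = int(float(row[idx["indi_drug_seq"]]))
        except (TypeError, ValueError):
            return
        rec.indications.append((seq, term))

    def _add_outc(rec: ReportRecord, row: list[str], idx: dict[str, int]) -> None:
        code = (row[idx["outc_cod"]] or "").strip().upper()
        if code in OUTCOME_CODES:
            rec.outcomes = rec.outcomes | {code}

    _join("DRUG", _add_drug)
    _join("REAC", _add_reac)
    _join("INDI", _add_indi)
    _join("OUTC", _add_outc)
    # THER and RPSR carry therapy dates / report sources; parsed for
    # provenance accounting only.
    for kind in ("THER", "RPSR"):
        for path in by_kind.get(kind, []):
            header, rows, rejected = _read_dollar_table(path)
            _check_columns(kind, header, path)
            store.provenance.append({
                "file": str(path), "table": kind, "quarter": _quarter_of(path),
                "parsed": len(rows) + rejected, "accepted": len(rows), "rejected": rejected,
            })

    store.reports = [records[pid] for pid in order]
    store.check_provenance()
    return store


# --- de-duplication -------------------------------------------------------


def _pid_cmp(x: str, y: str) -> int:
    """Compare primaryids numerically when both parse as ints, else lexically."""
    try:
        xi, yi = int(x), int(y)
    except (TypeError, ValueError):
        return (x > y) - (x < y)
    return (xi > yi) - (xi < yi)


def _version_cmp(a: ReportRecord, b: ReportRecord) -> int:
    # missing fda_dt sorts earliest so a dated version beats an undated one
    da, db = a.fda_dt or "", b.fda_dt or ""
    if da != db:
        return (da > db) - (da < db)
    return _pid_cmp(a.primaryid, b.primaryid)


def deduplicate(store: ReportStore) -> ReportStore:
    """Keep one report per CASEID: latest FDA_DT, then largest PRIMARYID.

    Idempotent and input-order invariant.  Reports with a blank caseid are
    kept as-is (each is its own case).
    """
    key = functools.cmp_to_key(_version_cmp)
    best: dict[str, ReportRecord] = {}
    order: list[str] = []
    passthrough: list[ReportRecord] = []
    for rec in store.reports:
        if not rec.caseid:
            passthrough.append(rec)
            continue
        cur = best.get(rec.caseid)
        if cur is None:
            best[rec.caseid] = rec
            order.append(rec.caseid)
        elif key(rec) > key(cur):
            best[rec.caseid] = rec
    # deterministic order regardless of input permutation
    survivors = sorted(
        [best[c] for c in order] + passthrough,
        key=lambda r: (r.caseid, r.primaryid),
    )
    out = ReportStore(reports=survivors, provenance=list(store.provenance),
                      deduplicated=True)
    seen = [r.caseid for r in out.reports if r.caseid]
    if len(seen) != len(set(seen)):  # consistency check per FDA guidance
        raise AssertionError("de-duplication left duplicate caseids")
    return out


# --- columnar round-trip --------------------------------------------------

_STORE_FILES = ("reports.tsv", "drugs.tsv", "events.tsv", "indications.tsv",
                "provenance.json")


def write_store(store: ReportStore, path: str | Path) -> Path:
    """Serialize a store to a directory of TSV files + a JSON sidecar."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    rep_rows, drug_rows, ev_rows, ind_rows = [], [], [], []
    for r in store.reports:
        rep_rows.append({
            "primaryid": r.primaryid, "caseid": r.caseid, "fda_dt": r.fda_dt,
            "sex": r.sex, "age_years": r.age_years, "weight_kg": r.weight_kg,
            "reporter_country": r.reporter_country, "reporter_type": r.reporter_type,
            "outcomes": ";".join(sorted(r.outcomes)),
        })
        for d in r.drugs:
            drug_rows.append({
                "primaryid": r.primaryid, "drug_seq": d.drug_seq, "role": d.role,
                "verbatim_name": d.verbatim_name, "prod_ai": d.prod_ai,
                "matched_drug_id": d.matched_drug_id,
            })
        for pt in sorted(r.events):
            ev_rows.append({"primaryid": r.primaryid, "pt": pt})
        for seq, term in r.indications:
            ind_rows.append({"primaryid": r.primaryid, "indi_drug_seq": seq,
                             "indi_pt": term})
    cols = {
        "reports.tsv": (rep_rows, ["primaryid", "caseid", "fda_dt", "sex",
                                   "age_years", "weight_kg", "reporter_country",
                                   "reporter_type", "outcomes"]),
        "drugs.tsv": (drug_rows, ["primaryid", "drug_seq", "role",
                                  "verbatim_name", "prod_ai", "matched_drug_id"]),
        "events.tsv": (ev_rows, ["primaryid", "pt"]),
        "indications.tsv": (ind_rows, ["primaryid", "indi_drug_seq", "indi_pt"]),
    }
    for name, (rows, columns) in cols.items():
        pd.DataFrame(rows, columns=columns).to_csv(out / name, sep="\t", index=False)
    (out / "provenance.json").write_text(json.dumps(
        {"provenance": store.provenance, "deduplicated": store.deduplicated},
        indent=1))
    return out


def load_store(path: str | Path) -> ReportStore:
    """Inverse of :func:`write_store`; round-trips field-for-field."""
    src = Path(path)
    rep = pd.read_csv(src / "reports.tsv", sep="\t", dtype={"primaryid": str,
                      "caseid": str, "fda_dt": str, "outcomes": str})
    drugs = pd.read_csv(src / "drugs.tsv", sep="\t", dtype=str)
    events = pd.read_csv(src / "events.tsv", sep="\t", dtype=str)
    inds = pd.read_csv(src / "indications.tsv", sep="\t", dtype=str)
    meta = json.loads((src / "provenance.json").read_text())

    def _groups(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
        if df.empty:
            return {}
        return dict(tuple(df.groupby("primaryid", sort=False)))

    gd, ge, gi = _groups(drugs), _groups(events), _groups(inds)
    reports = []
    for row in rep.itertuples(index=False):
        pid = row.primaryid
        dlist = []
        if pid in gd:
            for d in gd[pid].itertuples(index=False):
                dlist.append(DrugMention(
                    verbatim_name=d.verbatim_name if pd.notna(d.verbatim_name) else "",
                    role=d.role, drug_seq=int(d.drug_seq),
                    prod_ai=d.prod_ai if pd.notna(d.prod_ai) else None,
                    matched_drug_id=(d.matched_drug_id
                                     if pd.notna(d.matched_drug_id) else None)))
        evs = frozenset(ge[pid]["pt"]) if pid in ge else frozenset()
        ilist = ([(int(t.indi_drug_seq), t.indi_pt)
                  for t in gi[pid].itertuples(index=False)] if pid in gi else [])
        outc = frozenset((row.outcomes or "").split(";")) - {""} \
            if isinstance(row.outcomes, str) else frozenset()
        reports.append(ReportRecord(
            primaryid=pid, caseid=row.caseid,
            fda_dt=row.fda_dt if pd.notna(row.fda_dt) else None,
            sex=row.sex,
            age_years=float(row.age_years) if pd.notna(row.age_years) else None,
            weight_kg=float(row.weight_kg) if pd.notna(row.weight_kg) else None,
            reporter_country=(row.reporter_country
                              if pd.notna(row.reporter_country) else None),
            reporter_type=row.reporter_type,
            outcomes=outc, drugs=dlist, events=evs, indications=ilist))
    return ReportStore(reports=reports, provenance=meta["provenance"],
                       deduplicated=meta["deduplicated"])
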