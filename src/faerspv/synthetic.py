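"""FAERS-shaped synthetic corpora with planted disproportionality signals.

The generator emits the seven ``$``-delimited quarterly tables (DEMO, DRUG,
REAC, INDI, OUTC, THER, RPSR) plus a ground-truth table and a mock PT->SOC
map, so the whole pipeline is testable without any download.  Statistical
structure: each report draws one primary-suspect drug by exposure
probability (panel agent or background drug), then each PT independently
with its background probability — multiplied by rho (capped at 0.99) when
the (drug, PT) pair is planted.  Duplicates mimic FAERS case versioning:
a fraction of cases is re-emitted with a new, larger PRIMARYID and a later
FDA_DT.  The default configuration mirrors the study panel: 14 drugs across
5 target classes with class-shared plus drug-unique planted PT blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import SignalMatrix

__all__ = ["DrugSpec", "PtSpec", "PlantedSignal", "SynthConfig", "TruthTable",
           "GeneratedCorpus", "RecoveryResult", "default_config",
           "generate_corpus", "evaluate_recovery"]


@dataclass(frozen=True)
class DrugSpec:
    drug_id: str
    target_class: str
    exposure_prob: float
    name_variants: tuple[str, ...]  # verbatim spellings emitted in DRUG rows


@dataclass(frozen=True)
class PtSpec:
    name: str
    soc: str
    background_prob: float


@dataclass(frozen=True)
class PlantedSignal:
    drug_id: str
    pt: str
    rho: float  # reporting-rate multiplier >= 1


@dataclass
class SynthConfig:
    """Full description of one synthetic corpus (seed included)."""

    n_reports: int
    drugs: list[DrugSpec]
    pts: list[PtSpec]
    planted: list[PlantedSignal]
    n_background_drugs: int = 20
    duplicate_fraction: float = 0.05
    missingness: dict[str, float] = field(default_factory=lambda: {
        "sex": 0.05, "age": 0.15, "weight": 0.30,
        "reporter_country": 0.10, "reporter_type": 0.05,
    })
    nsclc_indication_prob: float = 0.9  # panel reports carrying a qualifying term
    concomitant_prob: float = 0.30
    secondary_suspect_prob: float = 0.02
    date_start: str = "2004-01-01"
    date_end: str = "2025-06-30"
    seed: int = 0

    def validate(self) -> None:
        for d in self.drugs:
            if not (0.0 < d.exposure_prob < 1.0):
                raise ValueError(f"exposure_prob for {d.drug_id} outside (0,1)")
        if sum(d.exposure_prob for d in self.drugs) >= 1.0:
            raise ValueError("panel exposure probabilities sum to >= 1")
        for p in self.pts:
            if not (0.0 < p.background_prob < 1.0):
                raise ValueError(f"background_prob for {p.name} outside (0,1)")
        if not (0.0 <= self.duplicate_fraction < 1.0):
            raise ValueError("duplicate_fraction outside [0,1)")
        seen = set()
        drug_ids = {d.drug_id for d in self.drugs}
        pt_names = {p.name for p in self.pts}
        for pl in self.planted:
            if pl.rho < 1.0:
                raise ValueError(f"rho < 1 for planted pair {pl}")
            if pl.drug_id not in drug_ids or pl.pt not in pt_names:
                raise ValueError(f"planted pair references unknown drug/PT: {pl}")
            if (pl.drug_id, pl.pt) in seen:
                raise ValueError(f"duplicate planted pair {pl.drug_id}/{pl.pt}")
            seen.add((pl.drug_id, pl.pt))


_PANEL: list[tuple[str, str, tuple[str, ...]]] = [
    ("gefitinib", "EGFR", ("GEFITINIB", "IRESSA", "GEFITINIB TABLETS")),
    ("erlotinib", "EGFR", ("ERLOTINIB", "TARCEVA", "Erlotinib Hydrochloride")),
    ("afatinib", "EGFR", ("AFATINIB", "GILOTRIF", "AFATINIB DIMALEATE")),
    ("dacomitinib", "EGFR", ("DACOMITINIB", "VIZIMPRO")),
    ("osimertinib", "EGFR", ("OSIMERTINIB", "TAGRISSO", "Osimertinib Mesylate")),
    ("crizotinib", "ALK", ("CRIZOTINIB", "XALKORI")),
    ("ceritinib", "ALK", ("CERITINIB", "ZYKADIA")),
    ("alectinib", "ALK", ("ALECTINIB", "ALECENSA", "ALECTINIB HYDROCHLORIDE")),
    ("brigatinib", "ALK", ("BRIGATINIB", "ALUNBRIG")),
    ("lorlatinib", "ALK", ("LORLATINIB", "LORBRENA")),
    ("repotrectinib", "ROS1", ("REPOTRECTINIB", "AUGTYRO")),
    ("pralsetinib", "RET", ("PRALSETINIB", "GAVRETO")),
    ("selpercatinib", "RET", ("SELPERCATINIB", "RETEVMO")),
    ("adagrasib", "KRAS-G12C", ("ADAGRASIB", "KRAZATI")),
]

_SOC_NAMES = [
    "Skin and subcutaneous tissue disorders",
    "Gastrointestinal disorders",
    "Investigations",
    "Cardiac disorders",
    "Nervous system disorders",
    "Hepatobiliary disorders",
    "Respiratory disorders",
    "Eye disorders",
    "Metabolism and nutrition disorders",
    "General disorders",
]

#: default block sizes for the class-signature structure
SHARED_BLOCK = 6   # PTs planted for every drug of one class
UNIQUE_BLOCK = 4   # PTs planted for a single drug
PLANTED_PROB = 0.01  # background probability of planted PTs
_BG_PROB_CYCLE = (0.004, 0.008, 0.015)


def default_config(n_reports: int = 50_000, rho: float = 5.0, seed: int = 0,
                   n_pts: int = 200, exposure_prob: float = 0.018) -> SynthConfig:
    """The study-shaped default corpus: 14 drugs / 5 classes / 200 PTs.

    Each target class gets a shared planted block of 6 PTs and every drug a
    unique block of 4 PTs (disjoint across drugs), all at multiplier ``rho``;
    the remaining PTs are pure background noise.  At the defaults every
    planted pair has expected count about n*0.018*(rho*0.01) = 45 reports.
    """
    drugs = [DrugSpec(d, cls, exposure_prob, variants) for d, cls, variants in _PANEL]
    classes = list(dict.fromkeys(cls for _, cls, _ in _PANEL))
    n_shared = len(classes) * SHARED_BLOCK
    n_unique = len(drugs) * UNIQUE_BLOCK
    if n_pts < n_shared + n_unique + 20:
        raise ValueError("n_pts too small for the default planted structure")
    pts = []
    for i in range(n_pts):
        prob = PLANTED_PROB if i < n_shared + n_unique \
            else _BG_PROB_CYCLE[i % len(_BG_PROB_CYCLE)]
        pts.append(PtSpec(name=f"SYNTHETIC PT {i:03d}",
                          soc=_SOC_NAMES[i % len(_SOC_NAMES)],
                          background_prob=prob))
    planted = []
    for ci, cls in enumerate(classes):
        block = [pts[ci * SHARED_BLOCK + k].name for k in range(SHARED_BLOCK)]
        for drug in drugs:
            if drug.target_class == cls:
                planted += [PlantedSignal(drug.drug_id, pt, rho) for pt in block]
    for di, drug in enumerate(drugs):
        start = n_shared + di * UNIQUE_BLOCK
        planted += [PlantedSignal(drug.drug_id, pts[start + k].name, rho)
                    for k in range(UNIQUE_BLOCK)]
    return SynthConfig(n_reports=n_reports, drugs=drugs, pts=pts,
                       planted=planted, seed=seed)


@dataclass
class TruthTable:
    """Planted (drug, PT, rho) triples with expected and realized counts."""

    entries: pd.DataFrame  # drug, pt, rho, background_prob, expected_a, realized_a
    panel_drugs: list[str]
    pt_vocabulary: list[str]

    def planted_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.entries["drug"], self.entries["pt"]))


@dataclass
class GeneratedCorpus:
    """Paths of everything one generator run emitted."""

    directory: Path
    table_paths: dict[str, Path]
    truth: TruthTable
    truth_path: Path
    pt_soc_map_path: Path
    config: SynthConfig


def _date_strings(dates: np.ndarray) -> np.ndarray:
    return np.char.replace(np.datetime_as_string(dates, unit="D"), "-", "")


def generate_corpus(config: SynthConfig, out_dir: str | Path) -> GeneratedCorpus:
    """Emit one synthetic quarter of FAERS-dialect files plus ground truth.

    The same config (seed included) produces byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = config.n_reports
    n_panel = len(config.drugs)
    n_pts = len(config.pts)

    # --- exposure assignment ------------------------------------------------
    bg_names = [f"BACKGROUND DRUG {k:02d}" for k in range(config.n_background_drugs)]
    panel_p = np.array([d.exposure_prob for d in config.drugs])
    bg_mass = 1.0 - panel_p.sum()
    probs = np.concatenate([panel_p,
                            np.full(len(bg_names), bg_mass / len(bg_names))])
    drug_idx = rng.choice(len(probs), size=n, p=probs)

    # --- event draws --------------------------------------------------------
    base_p = np.array([p.background_prob for p in config.pts], dtype=np.float32)
    prob_by_drug = np.tile(base_p, (len(probs), 1))
    pt_col = {p.name: j for j, p in enumerate(config.pts)}
    drug_row = {d.drug_id: i for i, d in enumerate(config.drugs)}
    for pl in config.planted:
        eff = pl.rho * base_p[pt_col[pl.pt]]
        if eff >= 1.0:
            warnings.warn(f"rho*p >= 1 for {pl.drug_id}/{pl.pt}; capped at 0.99",
                          stacklevel=2)
            eff = 0.99
        prob_by_drug[drug_row[pl.drug_id], pt_col[pl.pt]] = eff
    P = prob_by_drug[drug_idx]  # (n, n_pts)
    events = rng.random(P.shape, dtype=np.float32) < P
    del P

    # --- identifiers, dates, demographics -----------------------------------
    caseid = np.arange(10_000_000, 10_000_000 + n)
    primaryid = caseid * 10 + 1
    d0 = np.datetime64(config.date_start)
    span = int((np.datetime64(config.date_end) - d0).astype(int))
    fda_dt = _date_strings(d0 + rng.integers(0, span + 1, size=n))
    sex = rng.choice(np.array(["F", "M"]), size=n, p=[0.55, 0.45])
    age = np.round(np.clip(rng.normal(64.0, 13.0, size=n), 18.0, 95.0), 0)
    age_cod = np.full(n, "YR")
    wt = np.round(np.clip(rng.normal(68.0, 16.0, size=n), 35.0, 140.0), 1)
    wt_cod = np.full(n, "KG")
    country = rng.choice(np.array(["US", "JP", "CN", "GB", "DE", "FR"]), size=n,
                         p=[0.45, 0.15, 0.12, 0.10, 0.09, 0.09])
    occp = rng.choice(np.array(["MD", "PH", "HP", "CN", "OT"]), size=n,
                      p=[0.30, 0.15, 0.20, 0.25, 0.10])

    def _blank(values: np.ndarray, frac: float) -> np.ndarray:
        values = values.astype(object)
        values[rng.random(n) < frac] = ""
        return values

    miss = config.missingness
    sex = _blank(sex, miss.get("sex", 0.0))
    age_out = _blank(age.astype(int).astype(str), miss.get("age", 0.0))
    wt_out = _blank(wt.astype(str), miss.get("weight", 0.0))
    country = _blank(country, miss.get("reporter_country", 0.0))
    occp = _blank(occp, miss.get("reporter_type", 0.0))

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt, "sex": sex,
        "age": age_out, "age_cod": age_cod, "wt": wt_out, "wt_cod": wt_cod,
        "occp_cod": occp, "reporter_country": country,
    })

    # --- DRUG / INDI rows ----------------------------------------------------
    variant_pick = rng.integers(0, 1 << 16, size=n)
    is_panel = drug_idx < n_panel
    drugname = np.empty(n, dtype=object)
    prod_ai = np.empty(n, dtype=object)
    for i, d in enumerate(config.drugs):
        m = drug_idx == i
        variants = np.array(d.name_variants, dtype=object)
        drugname[m] = variants[variant_pick[m] % len(variants)]
        prod_ai[m] = d.drug_id.upper()
    for k, name in enumerate(bg_names):
        m = drug_idx == n_panel + k
        drugname[m] = name
        prod_ai[m] = name
    drug_rows = [pd.DataFrame({"primaryid": primaryid, "drug_seq": 1,
                               "role_cod": "PS", "drugname": drugname,
                               "prod_ai": prod_ai})]
    conc = rng.random(n) < config.concomitant_prob
    drug_rows.append(pd.DataFrame({
        "primaryid": primaryid[conc], "drug_seq": 2, "role_cod": "C",
        "drugname": "ASPIRIN", "prod_ai": "ASPIRIN"}))
    ss = rng.random(n) < config.secondary_suspect_prob
    ss_pick = rng.integers(0, n_panel, size=int(ss.sum()))
    drug_rows.append(pd.DataFrame({
        "primaryid": primaryid[ss], "drug_seq": 3, "role_cod": "SS",
        "drugname": np.array([config.drugs[i].drug_id.upper() for i in ss_pick],
                             dtype=object),
        "prod_ai": np.array([config.drugs[i].drug_id.upper() for i in ss_pick],
                            dtype=object)}))
    drug = pd.concat(drug_rows, ignore_index=True)

    nsclc = is_panel & (rng.random(n) < config.nsclc_indication_prob)
    indi_term = np.where(nsclc, "NON-SMALL CELL LUNG CANCER",
                         np.where(rng.random(n) < 0.5, "HYPERTENSION",
                                  "DIABETES MELLITUS"))
    indi = pd.DataFrame({"primaryid": primaryid, "indi_drug_seq": 1,
                         "indi_pt": indi_term})

    # --- REAC rows -----------------------------------------------------------
    rep_i, pt_j = np.nonzero(events)
    pt_names = np.array([p.name for p in config.pts], dtype=object)
    reac = pd.DataFrame({"primaryid": primaryid[rep_i], "pt": pt_names[pt_j]})

    # --- OUTC / THER / RPSR --------------------------------------------------
    outc_frames = []
    for code, p_out in (("DE", 0.08), ("LT", 0.03), ("HO", 0.25), ("DS", 0.05),
                        ("CA", 0.005), ("RI", 0.02), ("OT", 0.30)):
        m = rng.random(n) < p_out
        outc_frames.append(pd.DataFrame({"primaryid": primaryid[m],
                                         "outc_cod": code}))
    outc = pd.concat(outc_frames, ignore_index=True).sort_values(
        "primaryid", kind="stable", ignore_index=True)
    ther = pd.DataFrame({"primaryid": primaryid, "dsg_drug_seq": 1,
                         "start_dt": fda_dt})
    rpsr = pd.DataFrame({"primaryid": primaryid,
                         "rpsr_cod": rng.choice(np.array(["FGN", "HP", "CSM"]),
                                                size=n, p=[0.2, 0.5, 0.3])})

    # --- duplicate case versions --------------------------------------------
    n_dup = int(round(config.duplicate_fraction * n))
    frames = {"DEMO": demo, "DRUG": drug, "REAC": reac, "INDI": indi,
              "OUTC": outc, "THER": ther, "RPSR": rpsr}
    if n_dup > 0:
        dup_rows = np.sort(rng.choice(n, size=n_dup, replace=False))
        old_pid = primaryid[dup_rows]
        new_pid = caseid[dup_rows] * 10 + 2
        base_dates = np.array([np.datetime64(f"{s[:4]}-{s[4:6]}-{s[6:]}")
                               for s in fda_dt[dup_rows]])
        later = _date_strings(base_dates + rng.integers(1, 180, size=n_dup))
        remap = dict(zip(old_pid.tolist(), new_pid.tolist()))
        for kind in frames:
            df = frames[kind]
            m = df["primaryid"].isin(old_pid)
            dup = df.loc[m].copy()
            dup["primaryid"] = dup["primaryid"].map(remap)
            if kind == "DEMO":
                date_map = dict(zip(new_pid.tolist(), later.tolist()))
                dup["fda_dt"] = dup["primaryid"].map(date_map)
            frames[kind] = pd.concat([df, dup], ignore_index=True)

    # --- write ---------------------------------------------------------------
    paths: dict[str, Path] = {}
    for kind, df in frames.items():
        path = out / f"{kind}25Q2.txt"
        df.to_csv(path, sep="$", index=False, lineterminator="\n")
        paths[kind] = path

    soc_map = pd.DataFrame({"pt": [p.name for p in config.pts],
                            "soc": [p.soc for p in config.pts]})
    map_path = out / "pt_soc_map.tsv"
    soc_map.to_csv(map_path, sep="\t", index=False)

    # --- ground truth (realized counts on base cases) ------------------------
    truth_rows = []
    for pl in config.planted:
        j = pt_col[pl.pt]
        di = drug_row[pl.drug_id]
        p_bg = float(base_p[j])
        eff = min(pl.rho * p_bg, 0.99)
        realized = int(np.count_nonzero(events[drug_idx == di, j]))
        truth_rows.append({
            "drug": pl.drug_id, "pt": pl.pt, "rho": pl.rho,
            "background_prob": p_bg,
            "expected_a": n * config.drugs[di].exposure_prob * eff,
            "realized_a": realized,
        })
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["drug", "pt", "rho", "background_prob", "expected_a", "realized_a"])
    truth_path = out / "truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False)
    truth = TruthTable(entries=truth_df,
                       panel_drugs=[d.drug_id for d in config.drugs],
                       pt_vocabulary=[p.name for p in config.pts])
    return GeneratedCorpus(directory=out, table_paths=paths, truth=truth,
                           truth_path=truth_path, pt_soc_map_path=map_path,
                           config=config)


@dataclass
class RecoveryResult:
    """Pipeline recovery of planted signals."""

    sensitivity: float  # NaN when no planted pair qualifies
    false_positive_proportion: float
    n_planted_evaluated: int
    n_planted_called: int
    n_null_evaluated: int
    n_null_called: int


def evaluate_recovery(
    truth: TruthTable,
    called: SignalMatrix,
    min_expected_a: float = 10.0,
    min_rho: float = 5.0,
) -> RecoveryResult:
    """Sensitivity and false-positive proportion of the key-signal calls.

    Sensitivity is measured over planted pairs strong enough to be
    detectable (expected a >= ``min_expected_a`` and rho >= ``min_rho``);
    the false-positive proportion is over all evaluated non-planted
    (panel drug, vocabulary PT) pairs.
    """
    if set(called.drugs) != set(truth.panel_drugs):
        raise ValueError(
            f"drug label mismatch: calls {sorted(called.drugs)} vs "
            f"truth {sorted(truth.panel_drugs)}")
    key_sets = {d: called.signal_set(d) for d in called.drugs}
    planted = truth.planted_pairs()
    strong = [(r.drug, r.pt) for r in truth.entries.itertuples(index=False)
              if r.expected_a >= min_expected_a and r.rho >= min_rho]
    n_called = sum(pt in key_sets[d] for d, pt in strong)
    sens = n_called / len(strong) if strong else float("nan")
    n_null = n_null_called = 0
    for d in truth.panel_drugs:
        for pt in truth.pt_vocabulary:
            if (d, pt) in planted:
                continue
            n_null += 1
            if pt in key_sets[d]:
                n_null_called += 1
    fpp = n_null_called / n_null if n_null else float("nan")
    return RecoveryResult(sensitivity=sens, false_positive_proportion=fpp,
                          n_planted_evaluated=len(strong), n_planted_called=n_called,
                          n_null_evaluated=n_null, n_null_called=n_null_called)
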