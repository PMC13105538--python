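"""Drug–SOC–PT atlas: grouping key PT signals by System Organ Class.

MedDRA content is licensed, so the PT -> primary-SOC mapping is supplied by
the user as a two-column file (the synthetic generator emits a mock one).
Multiaxiality is deliberately collapsed to a single primary SOC per PT so
that per-drug PT counts are conserved across the SOC grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .signals import SignalMatrix, SignalScores

__all__ = ["UNMAPPED_SOC", "PtSocMap", "SocAtlas", "load_pt_soc_map",
           "build_atlas", "shared_pt_counts"]

UNMAPPED_SOC = "UNMAPPED"


@dataclass
class PtSocMap:
    """PT term -> primary SOC; unmapped PTs resolve to the UNMAPPED sentinel."""

    mapping: dict[str, str]

    def soc_of(self, pt: str) -> str:
        return self.mapping.get(pt, UNMAPPED_SOC)

    def __len__(self) -> int:
        return len(self.mapping)


def load_pt_soc_map(path: str | Path) -> PtSocMap:
    """Load a two-column tab-separated (pt, soc) file with a header row.

    Identical duplicate rows are collapsed; the same PT mapped to two
    different SOCs is a load error (each PT has exactly one primary SOC).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    if df.empty:
        raise ValueError(f"{path}: empty PT->SOC map")
    pt_col, soc_col = df.columns[:2]
    mapping: dict[str, str] = {}
    for pt, soc in zip(df[pt_col], df[soc_col]):
        if pt in mapping and mapping[pt] != soc:
            raise ValueError(
                f"{path}: PT {pt!r} mapped to both {mapping[pt]!r} and {soc!r}")
        mapping[pt] = soc
    return PtSocMap(mapping)


@dataclass
class SocAtlas:
    """Per drug: SOC -> [(PT, report count a)], plus SOC-level signal counts."""

    entries: dict[str, dict[str, list[tuple[str, int]]]]
    concordance_flags: dict[str, bool] = field(default_factory=dict)

    def soc_histogram(self, drug: str) -> dict[str, int]:
        """Number of key-signal PTs per SOC for one drug."""
        return {soc: len(pts) for soc, pts in self.entries[drug].items()}

    def total_signals(self, drug: str) -> int:
        return sum(len(pts) for pts in self.entries[drug].values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"drug": d, "soc": soc, "pt": pt, "a": a}
                for d, socs in self.entries.items()
                for soc, pts in socs.items() for pt, a in pts]
        return pd.DataFrame(rows, columns=["drug", "soc", "pt", "a"])


def build_atlas(
    matrix: SignalMatrix,
    scores: Mapping[str, Mapping[str, SignalScores]],
    pt_soc: PtSocMap,
    investigations_soc: str = "Investigations",
    organ_socs: tuple[str, ...] = (),
    min_pts_for_concordance: int = 2,
) -> SocAtlas:
    """Group each drug's key-signal PTs (with their a counts) by primary SOC.

    A drug is flagged for marker–organ concordance when the Investigations
    SOC (laboratory-marker PTs) and at least one configured organ SOC both
    hold >= ``min_pts_for_concordance`` key PTs — joint enrichment of a lab
    marker and its target organ.  Unmapped PTs are grouped under the
    sentinel SOC so totals are conserved.
    """
    entries: dict[str, dict[str, list[tuple[str, int]]]] = {}
    flags: dict[str, bool] = {}
    for drug in matrix.drugs:
        per_soc: dict[str, list[tuple[str, int]]] = {}
        for pt in sorted(matrix.signal_set(drug)):
            a = scores[drug][pt].a
            per_soc.setdefault(pt_soc.soc_of(pt), []).append((pt, a))
        entries[drug] = per_soc
        inv = len(per_soc.get(investigations_soc, []))
        organ = max((len(per_soc.get(s, [])) for s in organ_socs), default=0)
        flags[drug] = (inv >= min_pts_for_concordance
                       and organ >= min_pts_for_concordance)
    return SocAtlas(entries=entries, concordance_flags=flags)


def shared_pt_counts(matrix: SignalMatrix) -> pd.DataFrame:
    """Cross-drug sharing of key-signal PTs.

    Returns one row per PT with the number of drugs carrying it and the drug
    list; ``attrs`` carry the maximum sharing level, the PTs at each level
    k >= 2, and the all-drug intersection (empty unless one PT is a key
    signal for every drug on the panel).
    """
    counts = []
    for j, pt in enumerate(matrix.pts):
        drugs = [matrix.drugs[i] for i in range(len(matrix.drugs))
                 if matrix.values[i, j]]
        counts.append({"pt": pt, "n_drugs": len(drugs), "drugs": ";".join(drugs)})
    df = pd.DataFrame(counts, columns=["pt", "n_drugs", "drugs"])
    df = df.sort_values(["n_drugs", "pt"], ascending=[False, True],
                        ignore_index=True)
    max_k = int(df["n_drugs"].max()) if len(df) else 0
    by_level = {k: sorted(df.loc[df["n_drugs"] == k, "pt"])
                for k in range(2, max_k + 1)}
    n_drugs = len(matrix.drugs)
    intersection = sorted(df.loc[df["n_drugs"] == n_drugs, "pt"]) \
        if n_drugs > 0 and max_k == n_drugs else []
    df.attrs["max_sharing"] = max_k
    df.attrs["pts_by_level"] = by_level
    df.attrs["all_drug_intersection"] = intersection
    return df
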