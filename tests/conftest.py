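"""Shared fixtures: tiny hand-written FAERS tables and one full-scale
synthetic pipeline run reused across end-to-end tests."""

from __future__ import annotations

from pathlib import Path

import pytest

import faerspv


def write_faers(tmp_path: Path, tables: dict[str, list[str]]) -> list[Path]:
    """Write ``$``-delimited tables; each value is a list of lines
    (header first).  Returns the file paths."""
    paths = []
    for kind, lines in tables.items():
        p = tmp_path / f"{kind}24Q1.txt"
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    return paths


DEMO_HEADER = ("primaryid$caseid$fda_dt$sex$age$age_cod$wt$wt_cod$"
               "occp_cod$reporter_country")
DRUG_HEADER = "primaryid$drug_seq$role_cod$drugname$prod_ai"
REAC_HEADER = "primaryid$pt"
INDI_HEADER = "primaryid$indi_drug_seq$indi_pt"
OUTC_HEADER = "primaryid$outc_cod"


@pytest.fixture()
def tiny_store(tmp_path):
    """Four reports: two osimertinib-PS, one osimertinib-SS, one unrelated."""
    paths = write_faers(tmp_path, {
        "DEMO": [
            DEMO_HEADER,
            "1001$100$20240101$F$67$YR$59$KG$MD$US",
            "1002$101$20240102$M$670$MON$154$LBS$CN$JP",
            "1003$102$20240103$F$$YR$$KG$PH$",
            "1004$103$20240104$$60$YR$70$KG$$GB",
        ],
        "DRUG": [
            DRUG_HEADER,
            "1001$1$PS$TAGRISSO$OSIMERTINIB",
            "1002$1$PS$Osimertinib Mesylate$OSIMERTINIB",
            "1003$1$SS$TAGRISSO$OSIMERTINIB",
            "1003$2$PS$ASPIRIN$ASPIRIN",
            "1004$1$PS$IBUPROFEN$IBUPROFEN",
        ],
        "REAC": [
            REAC_HEADER,
            "1001$Rash", "1001$Dry skin", "1002$Rash", "1003$Nausea",
            "1004$Headache",
        ],
        "INDI": [
            INDI_HEADER,
            "1001$1$NON-SMALL CELL LUNG CANCER",
            "1002$1$HYPERTENSION",
            "1003$1$NON-SMALL CELL LUNG CANCER",
        ],
        "OUTC": [OUTC_HEADER, "1001$DE", "1001$HO", "1002$HO"],
    })
    return faerspv.read_faers_tables(paths)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full pipeline run on the default 50 000-report synthetic corpus.

    Session-scoped because it takes tens of seconds; every end-to-end
    check (planted-signal recovery, network structure, shared-PT analysis)
    reads from this single run.
    """
    out = tmp_path_factory.mktemp("full_run")
    cfg = faerspv.RunConfig(output_dir=str(out), seed=1)
    return faerspv.run_all(cfg)


@pytest.fixture(scope="session")
def default_classes():
    return faerspv.default_drug_dictionary().classes
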