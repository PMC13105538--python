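"""Generate a small FAERS-shaped corpus, parse it, and de-duplicate cases.

The generator plants known drug-event signals and injects duplicate case
versions (same CASEID, larger PRIMARYID, later FDA_DT), mimicking how FAERS
re-publishes updated reports.  De-duplication must restore exactly one
report per case, keeping the latest version.
"""

import tempfile

import faerspv

with tempfile.TemporaryDirectory() as tmp:
    config = faerspv.default_config(n_reports=5000, seed=42)
    config.duplicate_fraction = 0.10
    corpus = faerspv.generate_corpus(config, tmp)
    print(f"emitted tables: {sorted(corpus.table_paths)}")

    store = faerspv.read_faers_tables(corpus.table_paths.values())
    print(f"parsed reports (incl. duplicate versions): {len(store)}")

    deduped = faerspv.deduplicate(store)
    print(f"after de-duplication: {len(deduped)} reports, "
          f"{len(set(deduped.caseids()))} distinct cases")

# The 500 extra rows are newer versions of existing cases; de-duplication
# keeps the later FDA_DT version of each, so exactly 5000 cases survive.
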