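"""End-to-end orchestration: ingest -> dedup -> cohorts -> signals -> atlas
-> similarity network, with a run manifest and reproducible outputs.

All randomness flows from the single config seed; re-running the same config
produces identical outputs.  Each stage is an importable function in its own
module, so partial reruns are done from Python (or from the serialized store
via :func:`faerspv.faers_io.load_store`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import cohort as cohort_mod
from . import faers_io, signals as signals_mod, simnet, synthetic

__all__ = ["RunConfig", "RunResult", "run_all"]

logger = logging.getLogger("faerspv")

SIGNAL_COLUMNS = ["drug", "pt", "a", "ror", "ror_lo", "ror_hi", "prr", "chi2",
                  "ic", "ic025", "ebgm", "eb05", "prr_flag", "ror_flag",
                  "ic_flag", "ebgm_flag", "key"]


@dataclass
class RunConfig:
    """Everything one pipeline run depends on (defaults mirror the study)."""

    output_dir: str = "faerspv_run"
    input_paths: list[str] | None = None  # FAERS files; None -> simulate
    synth: synthetic.SynthConfig | None = None
    pt_soc_map_path: str | None = None
    drug_dictionary_path: str | None = None
    indication_terms: list[str] | None = None
    require_indication: bool = False
    thresholds: signals_mod.Thresholds = field(default_factory=signals_mod.Thresholds)
    chi2_correction: str = "yates"
    bcpnn_method: str = "exact"
    backbone_percentiles: tuple[float, ...] = (70.0, 80.0, 90.0)
    main_percentile: float = 80.0
    top_k_by_count: int = 10
    top_k_by_ebgm: int = 5
    mgps_restarts: int = 3
    seed: int = 0

    def validate(self) -> None:
        for p in self.backbone_percentiles + (self.main_percentile,):
            if not (0.0 < p < 100.0):
                raise ValueError(f"percentile {p} outside (0,100)")
        if self.top_k_by_count < 1 or self.top_k_by_ebgm < 1:
            raise ValueError("top-k values must be >= 1")
        if self.drug_dictionary_path is not None and \
                not Path(self.drug_dictionary_path).exists():
            raise ValueError(f"drug dictionary not found: {self.drug_dictionary_path}")
        if self.input_paths is not None:
            missing = [p for p in self.input_paths if not Path(p).exists()]
            if missing:
                raise ValueError(f"input files not found: {missing}")

    def resolved_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synth is not None:
            d["synth"] = {"n_reports": self.synth.n_reports,
                          "seed": self.synth.seed,
                          "n_drugs": len(self.synth.drugs),
                          "n_pts": len(self.synth.pts),
                          "n_planted": len(self.synth.planted),
                          "duplicate_fraction": self.synth.duplicate_fraction}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                kwargs[f.name] = data[f.name]
        if "thresholds" in kwargs:
            kwargs["thresholds"] = signals_mod.Thresholds(**kwargs["thresholds"])
        if "backbone_percentiles" in kwargs:
            kwargs["backbone_percentiles"] = tuple(kwargs["backbone_percentiles"])
        return cls(**kwargs)


@dataclass
class RunResult:
    """Handles to every pipeline artifact, on disk and in memory."""

    run_dir: Path
    manifest: dict
    store: faers_io.ReportStore
    cohorts: dict[str, cohort_mod.Cohort]
    prior: signals_mod.MgpsPrior
    scores: dict[str, dict[str, signals_mod.SignalScores]]
    matrix: signals_mod.SignalMatrix
    soc_atlas: atlas_mod.SocAtlas | None
    shared: pd.DataFrame
    similarity: simnet.SimilarityMatrix
    backbones: dict[float, simnet.NetworkBackbone]
    embedding: simnet.MdsEmbedding
    recovery: synthetic.RecoveryResult | None


def _scores_frame(scores: dict[str, dict[str, signals_mod.SignalScores]]) -> pd.DataFrame:
    rows = []
    for drug, per_pt in scores.items():
        for pt, s in per_pt.items():
            rows.append({"drug": drug, "pt": pt, **{
                k: getattr(s, k) for k in SIGNAL_COLUMNS[2:]}})
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS)


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write every artifact under the run dir."""
    config.validate()
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {"seed": config.seed, "stages": {}}
    try:
        # --- stage: inputs -------------------------------------------------
        truth = None
        pt_soc_path = config.pt_soc_map_path
        if config.input_paths is None:
            synth_cfg = config.synth or synthetic.default_config(seed=config.seed)
            corpus = synthetic.generate_corpus(synth_cfg, run_dir / "corpus")
            input_paths = [str(p) for p in corpus.table_paths.values()]
            truth = corpus.truth
            pt_soc_path = pt_soc_path or str(corpus.pt_soc_map_path)
            logger.info("simulated corpus: %d reports", synth_cfg.n_reports)
        else:
            input_paths = list(config.input_paths)
        manifest["stages"]["inputs"] = {"files": input_paths}

        # --- stage: ingest + dedup ----------------------------------------
        store = faers_io.read_faers_tables(input_paths)
        n_parsed = len(store)
        store = faers_io.deduplicate(store)
        logger.info("ingest: %d reports parsed, %d survive de-duplication "
                    "(%d duplicate versions dropped)",
                    n_parsed, len(store), n_parsed - len(store))
        manifest["stages"]["ingest"] = {
            "reports_parsed": n_parsed, "reports_after_dedup": len(store),
            "dropped_duplicates": n_parsed - len(store),
            "provenance": store.provenance,
        }

        # --- stage: cohorts ------------------------------------------------
        if config.drug_dictionary_path:
            dictionary = cohort_mod.DrugDictionary.from_yaml(config.drug_dictionary_path)
        else:
            dictionary = cohort_mod.default_drug_dictionary()
        ind_terms = (cohort_mod.IndicationTermSet(frozenset(config.indication_terms))
                     if config.indication_terms else
                     cohort_mod.default_indication_terms())
        cohorts = {}
        for drug_id in dictionary.drug_ids:
            cohorts[drug_id] = cohort_mod.build_cohort(
                store, drug_id, dictionary, indications=ind_terms,
                require_indication=config.require_indication)
            logger.info("cohort %s: %d reports", drug_id, len(cohorts[drug_id]))
        manifest["stages"]["cohorts"] = {d: len(c) for d, c in cohorts.items()}
        summaries = {}
        for drug_id, c in cohorts.items():
            summaries[drug_id] = cohort_mod.descriptive_summary(c)
            summaries[drug_id].to_csv(run_dir / f"descriptive_{drug_id}.tsv",
                                      sep="\t", index=False)
        pd.DataFrame({d: cohort_mod.missingness_profile(c)
                      for d, c in cohorts.items()}).to_csv(
            run_dir / "missingness.tsv", sep="\t")

        # --- stage: signals -------------------------------------------------
        tables = {d: signals_mod.contingency_tables(store, c)
                  for d, c in cohorts.items()}
        flat = [t for per in tables.values() for t in per.values()]
        prior = signals_mod.fit_mgps_prior(flat, n_restarts=config.mgps_restarts,
                                           seed=config.seed)
        logger.info("MGPS prior: %s (loglik %.2f)", prior, prior.loglik)
        scores = {
            d: {pt: signals_mod.compute_scores(
                    t, prior, thresholds=config.thresholds,
                    chi2_correction=config.chi2_correction,
                    bcpnn_method=config.bcpnn_method)
                for pt, t in per.items()}
            for d, per in tables.items()}
        matrix = signals_mod.signal_matrix(scores)
        sizes = matrix.set_sizes
        logger.info("key-signal set sizes: %s", sizes)
        manifest["stages"]["signals"] = {
            "prior": {k: getattr(prior, k) for k in
                      ("alpha1", "beta1", "alpha2", "beta2", "p", "loglik")},
            "set_sizes": sizes,
        }
        sig_df = _scores_frame(scores)
        sig_df.to_csv(run_dir / "signals.tsv", sep="\t", index=False)
        top = []
        for d in matrix.drugs:
            top += [{"drug": d, "rank_by": "count", "rank": i + 1, "pt": pt}
                    for i, pt in enumerate(signals_mod.rank_signals(
                        scores[d], by="count", k=config.top_k_by_count))]
            top += [{"drug": d, "rank_by": "ebgm", "rank": i + 1, "pt": pt}
                    for i, pt in enumerate(signals_mod.rank_signals(
                        scores[d], by="ebgm", k=config.top_k_by_ebgm))]
        pd.DataFrame(top, columns=["drug", "rank_by", "rank", "pt"]).to_csv(
            run_dir / "top_signals.tsv", sep="\t", index=False)

        # --- stage: atlas ----------------------------------------------------
        soc_atlas = None
        if pt_soc_path:
            pt_soc = atlas_mod.load_pt_soc_map(pt_soc_path)
            soc_atlas = atlas_mod.build_atlas(matrix, scores, pt_soc)
            soc_atlas.to_frame().to_csv(run_dir / "atlas.tsv", sep="\t", index=False)
            (run_dir / "soc_histograms.json").write_text(json.dumps(
                {d: soc_atlas.soc_histogram(d) for d in matrix.drugs}, indent=1))
        shared = atlas_mod.shared_pt_counts(matrix)
        shared.to_csv(run_dir / "shared_pts.tsv", sep="\t", index=False)
        manifest["stages"]["atlas"] = {
            "max_sharing": shared.attrs["max_sharing"],
            "all_drug_intersection": shared.attrs["all_drug_intersection"],
        }

        # --- stage: similarity network ---------------------------------------
        classes = dictionary.classes
        sim = simnet.jaccard_matrix(matrix, classes=classes)
        pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels).to_csv(
            run_dir / "similarity.tsv", sep="\t")
        backbones = {}
        for pct in config.backbone_percentiles:
            bb = simnet.backbone(sim, pct)
            backbones[pct] = bb
            pd.DataFrame(bb.edges, columns=["source", "target", "weight"]).to_csv(
                run_dir / f"backbone_{int(pct)}.tsv", sep="\t", index=False)
            g = bb.to_graph(classes=classes, nodes=sim.labels)
            (run_dir / f"backbone_{int(pct)}.json").write_text(json.dumps({
                "threshold": bb.threshold, "percentile": pct,
                "nodes": [{"id": u, "target_class": g.nodes[u].get("target_class")}
                          for u in g.nodes],
                "edges": [{"source": u, "target": v, "weight": d["weight"]}
                          for u, v, d in g.edges(data=True)]}, indent=1))
        order = simnet.cluster_order(sim)
        (run_dir / "heatmap_order.txt").write_text("\n".join(order) + "\n")
        emb = simnet.mds_embed(sim)
        pd.DataFrame({"drug": emb.labels, "x": emb.coords[:, 0],
                      "y": emb.coords[:, 1],
                      "class": [classes.get(d) for d in emb.labels]}).to_csv(
            run_dir / "mds.tsv", sep="\t", index=False)
        manifest["stages"]["network"] = {
            "backbone_edges": {str(p): b.n_edges for p, b in backbones.items()},
            "negative_eigenvalue_mass": emb.negative_mass_fraction,
        }

        # --- stage: recovery (synthetic runs only) ----------------------------
        recovery = None
        if truth is not None:
            recovery = synthetic.evaluate_recovery(truth, matrix)
            manifest["stages"]["recovery"] = dataclasses.asdict(recovery)
            logger.info("recovery: sensitivity %.3f, false-positive proportion %.4f",
                        recovery.sensitivity, recovery.false_positive_proportion)

        (run_dir / "config_resolved.yaml").write_text(
            yaml.safe_dump(config.resolved_dict(), sort_keys=False))
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                          default=str))
        return RunResult(run_dir=run_dir, manifest=manifest, store=store,
                         cohorts=cohorts, prior=prior, scores=scores,
                         matrix=matrix, soc_atlas=soc_atlas, shared=shared,
                         similarity=sim, backbones=backbones, embedding=emb,
                         recovery=recovery)
    except Exception as exc:  # annotate the failing stage, keep partial outputs
        done = list(manifest["stages"])
        logger.error("pipeline aborted after stages %s: %s", done, exc)
        (run_dir / "manifest.json").write_text(json.dumps(
            {**manifest, "error": str(exc)}, indent=1, default=str))
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
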