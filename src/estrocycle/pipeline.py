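"""End-to-end orchestration of the estrous-cycle analysis.

Stage order mirrors the analysis design: differential expression and trend
encoding per tissue, tissue clustering and ECTT prioritisation, gene-set
over-representation, network hubness, TF activity inference with key-TF
selection, and finally the signature comparative analysis with PTSP
verdicts.  A single seed drives every stochastic stage through named
substreams, so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import deg, enrich, io, netcent, synthdata, tascomp, tfact
from .errors import InputError, InvalidConfigError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    ``input_dir`` must contain ``counts_<tissue>.tsv`` files, ``*.gmt``
    collections, ``network.tsv``, ``regulons.tsv`` and one
    ``tas_library_<tissue>/`` directory per tissue.
    """

    input_dir: str = "inputs"
    seed: int = 0
    fc_min: float = 1.0
    q_max: float = 0.05
    scc_threshold: float = 0.1
    redundancy_cut: float = 0.5
    min_overlap: int = 100
    min_tissues: int = 5
    min_share: int = 4
    k_ectts: int = 6
    B: int = 1000
    include_reproductive: bool = False

    def validate(self) -> None:
        positive = {
            "fc_min": self.fc_min,
            "q_max": self.q_max,
            "scc_threshold": self.scc_threshold,
            "redundancy_cut": self.redundancy_cut,
            "min_overlap": self.min_overlap,
            "min_tissues": self.min_tissues,
            "min_share": self.min_share,
            "k_ectts": self.k_ectts,
            "B": self.B,
        }
        for name, value in positive.items():
            if value <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {value}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_json(obj, path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def write_bundle(bundle: synthdata.StudyBundle, input_dir) -> None:
    """Serialise a synthetic study bundle into a pipeline input directory."""
    input_dir = Path(input_dir)
    input_dir.mkdir(parents=True, exist_ok=True)
    for tissue in bundle.tissues:
        prof_a, prof_b = bundle.profiles[tissue]
        io.write_counts(prof_a, prof_b, input_dir / f"counts_{tissue}.tsv")
        io.write_tas_library(bundle.libraries[tissue], input_dir / f"tas_library_{tissue}")
    by_collection: dict[str, list] = {}
    for gs in bundle.genesets:
        by_collection.setdefault(gs.collection, []).append(gs)
    for collection, sets in by_collection.items():
        enrich.write_gmt(sets, input_dir / f"genesets_{collection}.gmt")
    io.write_network(bundle.network, input_dir / "network.tsv")
    io.write_regulons(bundle.regulons, input_dir / "regulons.tsv")
    truth = {
        tissue: {
            "deg_signs": t.deg_signs,
            "correlated_tas": {k: list(v) for k, v in t.correlated_tas.items()},
            "active_tfs": t.active_tfs,
            "hub_ids": list(t.hub_ids),
            "protective_phase": t.protective_phase,
        }
        for tissue, t in bundle.truth.items()
    }
    truth["_planted_terms"] = bundle.planted_terms
    truth["_regulon_reference_tissue"] = bundle.regulon_reference_tissue
    _write_json(truth, input_dir / "planted_truth.json")


def validate_inputs(config: PipelineConfig) -> dict[str, Any]:
    """Report-only consistency check of gene ids across all inputs."""
    input_dir = Path(config.input_dir)
    report: dict[str, Any] = {"warnings": []}
    try:
        count_files = io.list_count_files(input_dir)
    except InputError as exc:
        report["warnings"].append(str(exc))
        return report
    genes: set[str] = set()
    for path in count_files:
        prof_a, _ = io.read_counts(path)
        genes |= set(prof_a.genes)
    report["n_genes"] = len(genes)

    def overlap(ids: set[str], label: str) -> None:
        frac = len(ids & genes) / len(ids) if ids else 0.0
        report[f"{label}_overlap"] = frac
        if frac < 0.5:
            report["warnings"].append(
                f"{label}: only {frac:.0%} of ids overlap the count matrices"
            )

    net_path = input_dir / "network.tsv"
    if net_path.exists():
        overlap(set(io.read_network(net_path).nodes), "network")
    reg_path = input_dir / "regulons.tsv"
    if reg_path.exists():
        regulons = io.read_regulons(reg_path)
        overlap({g for r in regulons for g, _ in r.targets}, "regulon_targets")
    for gmt in sorted(input_dir.glob("*.gmt")):
        try:
            sets = enrich.read_gmt(gmt)
        except InputError as exc:
            report["warnings"].append(str(exc))
            continue
        overlap({g for s in sets for g in s.members}, f"genesets_{gmt.stem}")
    return report


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Any]:
    """Run every stage from the files in ``config.input_dir``.

    Writes all tables and reports under ``outdir`` plus a run manifest, and
    returns the result bundle in memory.
    """
    config.validate()
    input_dir = Path(config.input_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not input_dir.exists():
        raise InputError(f"input directory not found: {input_dir}")

    # --- differential expression and trends -----------------------------
    log.info("stage deg: calling differential expression per tissue")
    ortholog_path = input_dir / "ortholog_map.tsv"
    ortholog_map = io.read_ortholog_map(ortholog_path) if ortholog_path.exists() else None
    profiles = {}
    deg_tables = {}
    trends = []
    universe = {}
    for path in io.list_count_files(input_dir):
        prof_a, prof_b = io.read_counts(path)
        tissue = prof_a.tissue
        profiles[tissue] = (prof_a, prof_b)
        table = deg.differential_expression(prof_a, prof_b, fc_min=config.fc_min, q_max=config.q_max)
        if ortholog_map is not None:
            table = deg.apply_ortholog_map(table, ortholog_map)
        table.to_csv(outdir / f"deg_{tissue}.tsv", sep="\t", index=False)
        deg_tables[tissue] = table
        trends.append(deg.trend_vector(table, tissue))
        universe[tissue] = set(table["gene"])
    tissues = sorted(profiles)
    if config.k_ectts > len(tissues):
        raise InvalidConfigError(
            f"k_ectts={config.k_ectts} exceeds the number of tissues ({len(tissues)})"
        )
    deg_counts = {t.tissue: len(t.trend) for t in trends}
    if len(trends) >= 2:
        cosine = deg.tissue_cosine_matrix(trends)
        cosine.to_csv(outdir / "tissue_cosine.tsv", sep="\t")
    else:
        cosine = None
    ectts = deg.select_ectts(deg_counts, k=config.k_ectts)
    _write_json({"ectts": ectts, "deg_counts": deg_counts}, outdir / "ectts.json")

    # --- enrichment ------------------------------------------------------
    log.info("stage enrich: over-representation analysis")
    genesets = []
    for gmt in sorted(input_dir.glob("*.gmt")):
        collection = gmt.stem.replace("genesets_", "")
        genesets.extend(enrich.read_gmt(gmt, collection=collection))
    if genesets:
        results = enrich.run_enrichment(trends, genesets, universe, q_max=config.q_max)
        results.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        shared = enrich.shared_terms(results, min_tissues=config.min_tissues)
        unions = enrich.term_deg_unions(results, shared)
        collections = {gs.id: gs.collection for gs in genesets}
        links = enrich.term_overlap_links(
            unions, collections=collections, hide_within=("GAD",)
        )
        _write_json(
            {"shared_terms": shared, "links": [list(l) for l in links]},
            outdir / "enrichment_report.json",
        )
    else:
        results = pd.DataFrame()

    # --- network hubness -------------------------------------------------
    net_path = input_dir / "network.tsv"
    hubness = pd.DataFrame()
    if net_path.exists():
        log.info("stage netcent: centralities and hubness tests")
        network = io.read_network(net_path)
        centralities = netcent.compute_centralities(network)
        centralities.to_csv(outdir / "centrality.tsv", sep="\t")
        frames = []
        for trend in trends:
            report = netcent.hubness_report(centralities, trend.trend.keys())
            report.insert(0, "tissue", trend.tissue)
            frames.append(report)
        hubness = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        hubness.to_csv(outdir / "hubness.tsv", sep="\t", index=False)

    # --- TF activity -----------------------------------------------------
    reg_path = input_dir / "regulons.tsv"
    tf_results: dict[str, pd.DataFrame] = {}
    key_tfs: list[str] = []
    expr_act = (float("nan"), float("nan"))
    if reg_path.exists():
        log.info("stage tfact: TF activity inference (B=%d)", config.B)
        regulons = io.read_regulons(reg_path)
        frames = []
        for trend in trends:
            table = tfact.infer_tf_activity(
                regulons, trend, trend.tissue, B=config.B, seed=config.seed, q_max=config.q_max
            )
            tf_results[trend.tissue] = table
            frames.append(table)
        pd.concat(frames, ignore_index=True).to_csv(outdir / "tf_activity.tsv", sep="\t", index=False)
        key_tfs = tfact.key_tf_selection(tf_results, ectts, min_share=config.min_share)
        expr_act = tfact.expression_activity_correlation(tf_results, deg_tables)
        _write_json(
            {
                "key_tfs": key_tfs,
                "expression_activity_scc": expr_act[0],
                "expression_activity_p": expr_act[1],
            },
            outdir / "key_tfs.json",
        )

    # --- TAS comparative analysis ---------------------------------------
    log.info("stage tascomp: signature matching and PTSP")
    hit_frames = []
    hits_by_tissue = {}
    label_summaries = {}
    for tissue in tissues:
        meta = input_dir / f"tas_library_{tissue}" / "library_metadata.tsv"
        if not meta.exists():
            continue
        library = io.read_tas_library(meta)
        library = tascomp.prune_redundant(
            library, scc_cut=config.redundancy_cut, min_overlap=config.min_overlap
        )
        prof_a, prof_b = profiles[tissue]
        query = tascomp.build_tas(prof_a, prof_b, tas_id=f"{tissue}_estrus_induced")
        hits = tascomp.match_library(
            query, library, scc_threshold=config.scc_threshold, min_overlap=config.min_overlap
        )
        hits_by_tissue[tissue] = hits
        hit_frames.append(hits.assign(tissue=tissue))
        label_summaries[tissue] = tascomp.label_hierarchy_summary(hits, library)
    if hit_frames:
        pd.concat(hit_frames, ignore_index=True).to_csv(outdir / "tas_hits.tsv", sep="\t", index=False)
        exclude = () if config.include_reproductive else tascomp.REPRODUCTIVE_TISSUES
        calls = tascomp.ptsp_calls(hits_by_tissue, exclude_tissues=exclude)
        _write_json({t: dataclasses.asdict(c) for t, c in calls.items()}, outdir / "ptsp.json")
        _write_json(label_summaries, outdir / "label_summary.json")
    else:
        calls = {}

    # manifest records the input directory by name only, so runs of the same
    # config + seed in different locations stay byte-identical
    portable = dataclasses.replace(config, input_dir=Path(config.input_dir).name)
    manifest = {
        "config": portable.to_dict(),
        "config_hash": _config_hash(portable),
        "seed": config.seed,
        "inputs": sorted(p.name for p in input_dir.iterdir()),
        "tissues": tissues,
    }
    _write_json(manifest, outdir / "manifest.json")
    return {
        "deg_tables": deg_tables,
        "trends": {t.tissue: t for t in trends},
        "cosine": cosine,
        "ectts": ectts,
        "enrichment": results,
        "hubness": hubness,
        "tf_results": tf_results,
        "key_tfs": key_tfs,
        "expression_activity": expr_act,
        "hits_by_tissue": hits_by_tissue,
        "ptsp": calls,
    }


def demo(
    outdir,
    seed: int = 0,
    sim_config: synthdata.SimConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
) -> dict[str, Any]:
    """Generate a synthetic study, run the full pipeline, and score recovery.

    Writes the synthetic inputs under ``<outdir>/inputs``, all stage
    outputs under ``<outdir>/results``, and a ``recovery_report.json``
    comparing the pipeline's calls against the planted truth.
    """
    outdir = Path(outdir)
    sim = sim_config or synthdata.SimConfig(seed=seed)
    if sim.seed != seed:
        sim = dataclasses.replace(sim, seed=seed)
    bundle = synthdata.simulate_study(sim)
    input_dir = outdir / "inputs"
    write_bundle(bundle, input_dir)

    config = pipeline_config or PipelineConfig()
    config = dataclasses.replace(
        config,
        input_dir=str(input_dir),
        seed=seed,
        k_ectts=min(config.k_ectts, sim.n_tissues),
        min_tissues=min(config.min_tissues, sim.n_tissues),
    )
    results = run_pipeline(config, outdir / "results")
    report = recovery_report(bundle, results)
    _write_json(report, outdir / "recovery_report.json")
    return {"bundle": bundle, "results": results, "recovery": report}


def recovery_report(bundle: synthdata.StudyBundle, results: dict[str, Any]) -> dict[str, Any]:
    """Score pipeline calls against the bundle's planted truth."""
    report: dict[str, Any] = {}

    sens, fdr = [], []
    for tissue in bundle.tissues:
        truth = bundle.truth[tissue]
        table = results["deg_tables"][tissue]
        called = set(table.loc[table["call"] != "none", "gene"])
        planted = set(truth.deg_signs)
        if planted:
            sens.append(len(called & planted) / len(planted))
        if called:
            fdr.append(len(called - planted) / len(called))
    report["deg_sensitivity"] = float(pd.Series(sens).mean()) if sens else None
    report["deg_fdr"] = float(pd.Series(fdr).mean()) if fdr else None

    reference = bundle.regulon_reference_tissue
    truth_ref = bundle.truth[reference]
    tf_table = results["tf_results"].get(reference, pd.DataFrame())
    if not tf_table.empty:
        called_tfs = set(tf_table.loc[tf_table["significant"], "tf"])
        planted_tfs = set(truth_ref.active_tfs)
        tp = len(called_tfs & planted_tfs)
        report["tf_recall"] = tp / len(planted_tfs) if planted_tfs else None
        report["tf_precision"] = tp / len(called_tfs) if called_tfs else None

    if truth_ref.hub_ids and "hubness" in results and not results["hubness"].empty:
        network = bundle.network
        hub_deg = [network.degree(h) for h in truth_ref.hub_ids]
        bg_deg = [network.degree(n) for n in network if n not in set(truth_ref.hub_ids)]
        report["hub_degree_p"] = netcent.hubness_test(hub_deg, bg_deg, "greater")

    matched, total = 0, 0
    for tissue, call in results["ptsp"].items():
        planted_phase = bundle.truth[tissue].protective_phase
        if not planted_phase or call.verdict == "indeterminate":
            continue
        total += 1
        expected = "estrus-protective" if planted_phase == "estrus" else "diestrus-protective"
        matched += call.verdict == expected
    report["ptsp_verdicts_scored"] = total
    report["ptsp_recovery_rate"] = matched / total if total else None

    enrichment = results.get("enrichment")
    if enrichment is not None and not enrichment.empty and bundle.planted_terms:
        sig_terms = set(enrichment.loc[enrichment["significant"], "term"])
        report["planted_term_recovery"] = len(sig_terms & set(bundle.planted_terms)) / len(
            bundle.planted_terms
        )
    return report
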