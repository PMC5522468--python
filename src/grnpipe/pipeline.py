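"""End-to-end pipeline orchestration with plain-file handoff between stages.

Stage order follows the analysis the package implements: normalization and
flooring -> differential expression -> hierarchical clustering -> tree-
ensemble network inference -> gold-standard calibration -> community
structure, centrality, correlation signing and enrichment.  Every run writes
its artifacts as TSV/GraphML/SIF plus a JSON manifest recording the config,
seed, library versions, per-stage row counts and artifact checksums, so a
run can be audited and reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import analysis as na
from . import calibrate as cal
from . import cluster as cl
from . import de as de_mod
from . import inference as inf
from . import io as eio

log = logging.getLogger("grnpipe")

__all__ = ["PipelineConfig", "run_pipeline", "real_data_benchmark", "write_report"]

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    counts: str = ""
    design: str = ""
    annotation: str = ""
    tf_list: str = ""
    gold_standard: str | None = None
    gene_sets: str | None = None

    use_positive_controls: bool = True
    use_housekeeping: bool = True
    low_expression_floor: float = 0.00004
    pseudocount: float = 1.0

    de_preset: str = "figure"
    t_test_variant: str = "student"
    bh_correct: bool = False

    k_clusters: int = 11
    linkage: str = "complete"

    n_trees: int = 1000
    standardize_targets: bool = True

    threshold_mode: str = "knee"  # manual | knee | top_k
    im_threshold: float | None = None
    top_k: int | None = None

    community_algorithm: str = "greedy_modularity"
    betweenness_directed: bool = True
    neighbor_genes: tuple[str, ...] = ()
    enrichment_alpha: float = 0.05

    seed: int = 0
    outdir: str = "run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "neighbor_genes" in raw and raw["neighbor_genes"] is not None:
            raw["neighbor_genes"] = tuple(raw["neighbor_genes"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("counts", "design", "annotation", "tf_list"):
            p = getattr(self, name)
            if not p or not pathlib.Path(p).exists():
                raise FileNotFoundError(f"config path {name}={p!r} does not exist")
        for name in ("gold_standard", "gene_sets"):
            p = getattr(self, name)
            if p and not pathlib.Path(p).exists():
                raise FileNotFoundError(f"config path {name}={p!r} does not exist")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_tf_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    cfg.validate_paths()
    outdir = pathlib.Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "versions": _versions(),
        "stages": [],
        "artifacts": {},
    }
    artifacts: dict[str, pathlib.Path] = {}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            snap = outdir / "failed_stage.json"
            snap.write_text(json.dumps({"stage": name, "error": str(exc)}, indent=2))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        return result

    def emit(name: str, path: pathlib.Path):
        artifacts[name] = path
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    # -- load -----------------------------------------------------------------
    def _load():
        design = eio.read_design(cfg.design)
        m = eio.read_counts(cfg.counts, design)
        ann = eio.read_annotation(cfg.annotation)
        tfs = _read_tf_list(cfg.tf_list)
        log.info("load: %d genes x %d samples, %d TFs", m.shape[0], m.shape[1], len(tfs))
        return m, ann, tfs

    m, ann, tfs = stage("load", _load)
    hk = tuple(a.gene for a in ann if a.is_housekeeping and a.gene in m.genes)
    pos = tuple(a.gene for a in ann if a.is_positive_control and a.gene in m.genes)

    # -- normalize + floor ----------------------------------------------------
    def _normalize():
        ncfg = eio.NormalizationConfig(
            positive_control_genes=pos if cfg.use_positive_controls else (),
            housekeeping_genes=hk if cfg.use_housekeeping else (),
            low_expression_floor=cfg.low_expression_floor,
            pseudocount=cfg.pseudocount,
        )
        if ncfg.positive_control_genes or ncfg.housekeeping_genes:
            norm = eio.normalize(m, ncfg)
        else:
            log.warning("normalize: no reference genes available; passing values through")
            norm = eio.ExpressionMatrix(m.values, m.design, "normalized", m.absent_genes)
        floored = eio.floor_low_expression(norm, cfg.low_expression_floor)
        log.info("normalize: %d genes, %d flagged absent", floored.shape[0], len(floored.absent_genes))
        path = outdir / "normalized.tsv"
        out = floored.values.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        return floored, path

    floored, p = stage("normalize", _normalize)
    emit("normalized", p)

    # analysis matrix excludes housekeeping/positive-control probes
    aux = set(hk) | set(pos)
    core_genes = [g for g in floored.genes if g not in aux]
    core = eio.ExpressionMatrix(
        floored.values.loc[core_genes], floored.design, "normalized", floored.absent_genes
    )

    # -- differential expression ----------------------------------------------
    def _de():
        thr = de_mod.DEThresholds.preset(cfg.de_preset)
        table = de_mod.de_table(core, thr, variant=cfg.t_test_variant, bh_correct=cfg.bh_correct)
        log.info("de: %d gene x timepoint rows, %d up, %d down", len(table),
                 int((table["call"] == "up").sum()), int((table["call"] == "down").sum()))
        path = outdir / "de.tsv"
        table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        return table, path

    de_table, p = stage("differential_expression", _de)
    emit("de", p)

    # -- hierarchical clustering ----------------------------------------------
    def _cluster():
        logm = eio.log_transform(core, cfg.pseudocount)
        k = min(cfg.k_clusters, logm.shape[0])
        assignment = cl.cluster_genes(logm, k=k, linkage=cfg.linkage)
        log.info("cluster: %d genes into %d clusters (%s linkage)", logm.shape[0], k, cfg.linkage)
        path = outdir / "clusters.tsv"
        assignment.frame().to_csv(path, sep="\t", index=False)
        tree_path = outdir / "cluster_tree.nwk"
        tree_path.write_text(cl.to_newick(assignment) + "\n")
        return assignment, path, tree_path

    assignment, p, tp = stage("expression_clustering", _cluster)
    emit("clusters", p)
    emit("cluster_tree", tp)

    # -- inference -------------------------------------------------------------
    def _infer():
        icfg = inf.InferenceConfig(
            n_trees=cfg.n_trees, seed=cfg.seed, standardize_targets=cfg.standardize_targets
        )
        regs = [t for t in tfs if t in core.genes]
        ranked = inf.infer_grn(core, regs, icfg)
        log.info("infer: %d candidate edges ranked (%d regulators)", len(ranked), len(regs))
        path = outdir / "edges_ranked.tsv"
        ranked.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        return ranked, path

    ranked, p = stage("grn_inference", _infer)
    emit("edges_ranked", p)

    # -- calibration -----------------------------------------------------------
    def _calibrate():
        curve = None
        if cfg.gold_standard:
            gs = cal.GoldStandard.read(cfg.gold_standard).restrict_to(set(core.genes))
            thresholds = sorted(set(np.quantile(ranked["im"], np.linspace(0, 0.999, 60))))
            curve = cal.sensitivity_curve(ranked, gs, thresholds)
            cpath = outdir / "calibration_curve.tsv"
            curve.points.to_csv(cpath, sep="\t", index=False, float_format=FLOAT_FMT)
            emit("calibration_curve", cpath)
        elif cfg.threshold_mode == "knee":
            raise ValueError("knee threshold selection requires a gold standard")
        else:
            log.warning("calibrate: no gold standard; sensitivity curve skipped")
        value = cfg.im_threshold if cfg.threshold_mode == "manual" else cfg.top_k
        result = cal.select_threshold(curve, cfg.threshold_mode, value, ranked=ranked)
        log.info("calibrate: mode=%s threshold=%.6g -> %d edges / %d nodes",
                 result.selection_mode, result.chosen_threshold, result.n_edges, result.n_nodes)
        net = cal.build_network(ranked, result)
        return result, net

    result, net = stage("network_calibration", _calibrate)

    # -- network analysis --------------------------------------------------------
    def _analyze():
        corr = na.pearson_matrix(core)
        signed = na.sign_edges(net, corr)
        partition = na.community_cluster(signed, algorithm=cfg.community_algorithm)
        records = na.centrality(signed, directed=cfg.betweenness_directed)
        log.info("analyze: %d modules (Q=%.4f), %d centrality records",
                 partition.n_modules, partition.modularity_q, len(records))

        paths = {}
        corr_path = outdir / "pearson.tsv"
        corr.to_csv(corr_path, sep="\t", float_format=FLOAT_FMT)
        paths["pearson"] = corr_path
        net_path = outdir / "network_edges.tsv"
        na.write_edge_tsv(signed, net_path)
        paths["network_edges"] = net_path
        na.write_graphml(signed, outdir / "network.graphml")
        paths["network_graphml"] = outdir / "network.graphml"
        na.write_sif(signed, outdir / "network.sif")
        paths["network_sif"] = outdir / "network.sif"
        mod_path = outdir / "modules.tsv"
        partition.frame().assign(modularity_q=partition.modularity_q).to_csv(
            mod_path, sep="\t", index=False, float_format=FLOAT_FMT
        )
        paths["modules"] = mod_path
        cen_path = outdir / "centrality.tsv"
        na.centrality_frame(records).to_csv(cen_path, sep="\t", index=False, float_format=FLOAT_FMT)
        paths["centrality"] = cen_path

        for gene in cfg.neighbor_genes:
            if gene not in signed:
                log.warning("analyze: neighbor gene %s not in network; skipped", gene)
                continue
            sub = na.first_neighbors(signed, gene, "both")
            np_path = outdir / f"neighbors_{gene}.tsv"
            na.write_edge_tsv(sub, np_path)
            paths[f"neighbors_{gene}"] = np_path

        if cfg.gene_sets:
            sets = na.read_gene_sets(cfg.gene_sets)
            enr = na.enrich_modules(partition, sets, universe=list(core.genes), alpha=cfg.enrichment_alpha)
            enr_path = outdir / "enrichment.tsv"
            na.enrichment_frame(enr).to_csv(enr_path, sep="\t", index=False, float_format=FLOAT_FMT)
            paths["enrichment"] = enr_path
        return signed, partition, records, paths

    signed, partition, records, paths = stage("network_analysis", _analyze)
    for name, path in paths.items():
        emit(name, path)

    manifest["summary"] = {
        "n_genes": core.shape[0],
        "n_samples": core.shape[1],
        "n_candidate_edges": int(len(ranked)),
        "im_threshold": result.chosen_threshold,
        "n_network_edges": result.n_edges,
        "n_network_nodes": result.n_nodes,
        "n_modules": partition.n_modules,
        "modularity_q": partition.modularity_q,
        "de_up": int((de_table["call"] == "up").sum()),
        "de_down": int((de_table["call"] == "down").sum()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _versions() -> dict[str, str]:
    import networkx
    import scipy
    import sklearn

    from . import __version__

    return {
        "grnpipe": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
    }


def real_data_benchmark(
    counts,
    design,
    annotation,
    tf_list,
    gold_standard=None,
    im_threshold: float = 0.006,
    top_k: int = 500,
    n_trees: int = 1000,
    seed: int = 0,
) -> dict:
    """Headline numbers for a user-supplied screen dataset.

    Normalizes and floors the supplied counts, infers the network, applies
    the given IM threshold, clusters the top-k edges into communities, and
    counts 6-h up-regulated transcripts under the stricter threshold preset.
    Returns a dict of the computed quantities.
    """
    designs = eio.read_design(design)
    m = eio.read_counts(counts, designs)
    ann = eio.read_annotation(annotation)
    hk = tuple(a.gene for a in ann if a.is_housekeeping and a.gene in m.genes)
    pos = tuple(a.gene for a in ann if a.is_positive_control and a.gene in m.genes)
    if hk or pos:
        m = eio.normalize(m, eio.NormalizationConfig(positive_control_genes=pos, housekeeping_genes=hk))
    else:
        m = eio.ExpressionMatrix(m.values, m.design, "normalized", m.absent_genes)
    m = eio.floor_low_expression(m, 0.00004)
    core_genes = [g for g in m.genes if g not in set(hk) | set(pos)]
    core = eio.ExpressionMatrix(m.values.loc[core_genes], m.design, "normalized", m.absent_genes)

    tfs = [t for t in _read_tf_list(tf_list) if t in core.genes]
    ranked = inf.infer_grn(core, tfs, inf.InferenceConfig(n_trees=n_trees, seed=seed))

    thr_res = cal.select_threshold(None, "manual", im_threshold, ranked=ranked)
    out = {
        "n_edges_at_threshold": thr_res.n_edges,
        "n_nodes_at_threshold": thr_res.n_nodes,
    }
    k = min(top_k, len(ranked))
    top = cal.build_network(ranked, cal.select_threshold(None, "top_k", k, ranked=ranked))
    partition = na.community_cluster(top)
    out["n_communities_top_k"] = partition.n_modules
    out["modularity_q_top_k"] = partition.modularity_q

    table = de_mod.de_table(core, de_mod.DEThresholds.preset("figure"))
    first_tp = min(core.timepoints)
    sel = table[(table["timepoint_hrs"] == first_tp) & (table["call"] == "up")]
    out["de_up_first_timepoint"] = int(len(sel))
    if gold_standard:
        gs = cal.GoldStandard.read(gold_standard).restrict_to(set(core.genes))
        curve = cal.sensitivity_curve(ranked, gs, [im_threshold])
        out["sensitivity_at_threshold"] = float(curve.points["sensitivity"].iloc[0])
    return out


def write_report(run_dir, path=None) -> str:
    """Render a markdown summary of a completed run directory."""
    run_dir = pathlib.Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    s = manifest["summary"]
    lines = [
        "# Pipeline run report",
        "",
        f"Seed: {manifest['seed']}",
        "",
        "## Summary",
        "",
        f"- genes x samples: {s['n_genes']} x {s['n_samples']}",
        f"- candidate edges ranked: {s['n_candidate_edges']}",
        f"- IM threshold: {s['im_threshold']:.6g} -> {s['n_network_edges']} edges, {s['n_network_nodes']} nodes",
        f"- communities: {s['n_modules']} (modularity Q = {s['modularity_q']:.4f})",
        f"- DE calls: {s['de_up']} up, {s['de_down']} down (all timepoints pooled)",
        "",
        "## Stage timings",
        "",
    ]
    for st in manifest["stages"]:
        lines.append(f"- {st['stage']}: {st['seconds']} s")
    de_path = run_dir / "de.tsv"
    if de_path.exists():
        table = pd.read_csv(de_path, sep="\t")
        called = table[table["call"] != "unchanged"].sort_values(["timepoint_hrs", "call", "gene"])
        lines += ["", "## Differential-expression calls", ""]
        if called.empty:
            lines.append("(none)")
        else:
            lines.append(called.to_string(index=False))
    text = "\n".join(lines) + "\n"
    out_path = pathlib.Path(path) if path else run_dir / "report.md"
    out_path.write_text(text)
    return str(out_path)
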