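"""End-to-end orchestration from a single configuration.

Stage order: simulate (or load) -> preprocess -> candidate network -> scored,
thresholded GRN -> differential expression -> seed-pair shortest paths ->
DE enrichment of path genes -> KNN/jackknife biomarker selection. Every stage
writes its artifact to the output directory and contributes counts to a
machine-readable JSON report; identical config + seed gives a byte-identical
report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import candidates as cand_mod
from . import classify, de, enrichment, grn, paths, preprocess, simulate as sim
from .matrix import (ExpressionMatrix, read_expression_matrix, read_feature_annotation,
                     read_gene_list, read_sample_metadata, write_expression_matrix)

logger = logging.getLogger("grnpath")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

DEFAULT_DE_CONTRASTS = {
    "SPN_vs_normal": (["SPN"], ["normal"]),
    "PanNET_vs_normal": (["PanNET"], ["normal"]),
    "PDAC_vs_normal": (["PDAC"], ["normal"]),
    "SPN_vs_PanNET": (["SPN"], ["PanNET"]),
    "SPN_vs_PDAC": (["SPN"], ["PDAC"]),
}

DEFAULT_CLASSIFY_CONTRASTS = {
    "SPN_vs_malignant": {"pools": {"malignant": ["PanNET", "PDAC"]}, "keep": ["SPN"]},
    "SPN_vs_PanNET": {"pools": {}, "keep": ["SPN", "PanNET"]},
    "SPN_vs_PDAC": {"pools": {}, "keep": ["SPN", "PDAC"]},
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of ``simulate`` / ``inputs`` set.

    ``inputs`` maps: mrna, mirna, metadata, annotation, seeds (paths) plus
    ``edges``: a list of [path, provenance] pairs.
    """

    outdir: str = "grnpath_out"
    simulate: sim.SyntheticConfig | None = None
    inputs: dict | None = None
    run_preprocess: bool = False          # log2 + quantile normalization of raw input
    correlation_samples: str = "disease"  # "disease" or "all"
    disease_class: str = "SPN"
    cutoff_grid: list = field(default_factory=lambda: [round(0.1 * i, 1) for i in range(10)])
    cutoff_tf: float = 0.8
    cutoff_mirna: float = 0.8
    de_p_threshold: float = 0.01
    de_fc_threshold: float = 2.0
    de_contrasts: dict = field(default_factory=lambda: dict(DEFAULT_DE_CONTRASTS))
    path_mode: str = "undirected"
    k_max: int = 3
    voting: str = "chou"
    k_plain: int = 3
    selection_strategy: str = "greedy"
    classify_contrasts: dict = field(default_factory=lambda: dict(DEFAULT_CLASSIFY_CONTRASTS))
    rng_seed: int = 0

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be configured")
        if self.correlation_samples not in ("disease", "all"):
            raise ValueError("correlation_samples must be 'disease' or 'all'")
        for c in (self.cutoff_tf, self.cutoff_mirna):
            if not (0.0 <= c < 1.0):
                raise ValueError(f"cutoffs must lie in [0, 1), got {c}")
        if not (0.0 < self.de_p_threshold <= 1.0) or self.de_fc_threshold < 1.0:
            raise ValueError("invalid DE thresholds")
        if self.path_mode not in ("undirected", "directed"):
            raise ValueError("path_mode must be 'undirected' or 'directed'")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulate is not None:
            out["simulate"] = dataclasses.asdict(self.simulate)
        return out

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "simulate" in raw and raw["simulate"] is not None:
        raw["simulate"] = sim.SyntheticConfig(**raw["simulate"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    # normalize contrast lists loaded from YAML into tuples
    cfg = PipelineConfig(**raw)
    cfg.de_contrasts = {k: (list(v[0]), list(v[1])) for k, v in cfg.de_contrasts.items()}
    return cfg


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        cfg = dataclasses.replace(config.simulate, rng_seed=config.rng_seed)
        ds = sim.simulate(cfg)
        sim.write_dataset(ds, outdir / "inputs")
        return ds.mrna, ds.mirna, ds.metadata, ds.annotation, ds.candidate_edges, ds.seeds
    paths_cfg = config.inputs
    required = {"mrna", "mirna", "metadata", "annotation", "seeds", "edges"}
    missing = required - set(paths_cfg)
    if missing:
        raise ValueError(f"inputs block missing keys: {sorted(missing)}")
    scale = "raw" if config.run_preprocess else "log2"
    mrna = read_expression_matrix(paths_cfg["mrna"], scale_hint=scale)
    mirna = read_expression_matrix(paths_cfg["mirna"], scale_hint=scale)
    metadata = read_sample_metadata(paths_cfg["metadata"])
    annotation = read_feature_annotation(paths_cfg["annotation"])
    edges = cand_mod.load_edges([(p, prov) for p, prov in paths_cfg["edges"]], annotation)
    seeds = read_gene_list(paths_cfg["seeds"])
    return mrna, mirna, metadata, annotation, edges, seeds


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    try:
        config.validate()
    except ValueError as exc:
        raise PipelineError("config", str(exc)) from exc
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "config_hash": config.config_hash(),
                    "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # --- inputs / simulation ---------------------------------------------
    name = stage("inputs")
    try:
        mrna, mirna, metadata, annotation, edge_list, seeds = _load_inputs(config, outdir)
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    report["stages"][name] = {
        "n_mrna_features": mrna.shape[0], "n_mirna_features": mirna.shape[0],
        "n_samples": len(metadata), "n_seeds": len(seeds),
    }

    # --- preprocessing ----------------------------------------------------
    if config.run_preprocess:
        name = stage("preprocess")
        try:
            mrna = preprocess.quantile_normalize(preprocess.log2_transform(mrna, offset=1.0))
            mirna = preprocess.quantile_normalize(preprocess.log2_transform(mirna, offset=1.0))
            write_expression_matrix(mrna, outdir / "mrna_normalized.tsv")
            write_expression_matrix(mirna, outdir / "mirna_normalized.tsv")
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        report["stages"][name] = {"applied": True}

    # --- candidate network ------------------------------------------------
    name = stage("candidate_network")
    try:
        network = cand_mod.merge([edge_list])
        network.write_tsv(outdir / "candidate_edges.tsv")
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    report["stages"][name] = {
        "n_edges": len(network),
        "category_counts": network.category_counts,
        "n_validated": network.n_validated,
    }

    # --- GRN --------------------------------------------------------------
    name = stage("grn")
    try:
        if config.correlation_samples == "disease":
            subset = [s for s in metadata.index if metadata[s] == config.disease_class]
        else:
            subset = None
        scored = grn.score_edges(network.edges, mrna, mirna, sample_subset=subset)
        scan = grn.scan_cutoffs(scored, config.cutoff_grid)
        scan.to_csv(outdir / "cutoff_scan.tsv", sep="\t", index=False)
        net = grn.build_grn(scored, cutoff_tf=config.cutoff_tf,
                            cutoff_mirna=config.cutoff_mirna)
        net.write_tsv(outdir / "grn.tsv")
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    report["stages"][name] = net.summary()

    # --- differential expression -----------------------------------------
    name = stage("differential_expression")
    de_frames: dict[str, pd.DataFrame] = {}
    try:
        for cname, (ga, gb) in config.de_contrasts.items():
            frames = []
            for m in (mrna, mirna):
                frames.append(de.call_de(m, metadata, (ga, gb),
                                         p_threshold=config.de_p_threshold,
                                         fc_threshold=config.de_fc_threshold))
            frame = pd.concat(frames, ignore_index=True)
            frame.to_csv(outdir / f"de_{cname}.tsv", sep="\t", index=False)
            de_frames[cname] = frame
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    report["stages"][name] = {
        cname: int(frame["is_de"].sum()) for cname, frame in de_frames.items()}

    # --- shortest paths ---------------------------------------------------
    name = stage("shortest_paths")
    try:
        graph = paths.to_path_graph(net, mode=config.path_mode)
        path_results = paths.seed_pair_paths(graph, seeds)
        paths.write_paths_tsv(path_results, outdir / "shortest_paths.tsv")
        roles = net.nodes
        path_genes = paths.extract_path_genes(path_results, seeds, roles)
        subnet = paths.export_subnetwork(path_results, seeds, roles)
        subnet.to_csv(outdir / "path_subnetwork.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    report["stages"][name] = {
        "n_paths": len(path_results),
        "n_path_genes": len(path_genes.roles),
        "path_gene_roles": path_genes.role_counts(),
    }

    # --- enrichment -------------------------------------------------------
    name = stage("enrichment")
    try:
        disease_contrast = f"{config.disease_class}_vs_normal"
        enr: dict[str, dict] = {}
        if disease_contrast in de_frames:
            de_set = set(de_frames[disease_contrast].loc[
                lambda f: f["is_de"], "feature_id"])
            roles = net.nodes
            reports = []
            for role in ("TF", "miRNA"):
                candidate = {g for g, r in path_genes.roles.items() if r == role}
                background = {n for n, r in roles.items() if r == role} | candidate
                if not candidate:
                    enr[role] = {"p_value": None, "note": "no candidates of this role"}
                    continue
                rep = enrichment.enrichment_report(candidate, de_set, background)
                rep.insert(0, "role", role)
                reports.append(rep)
                enr[role] = {
                    "p_value": float(rep.loc[rep["convention"] == "disjoint_background",
                                             "p_value"].iloc[0]),
                }
            if reports:
                pd.concat(reports, ignore_index=True).to_csv(
                    outdir / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    report["stages"][name] = enr

    # --- biomarker classification ----------------------------------------
    name = stage("classification")
    try:
        candidate_genes = sorted(set(seeds) | set(path_genes.roles))
        in_matrix = [g for g in candidate_genes
                     if g in mrna.values.index or g in mirna.values.index]
        merged = ExpressionMatrix(
            pd.concat([mrna.values, mirna.values]), scale="log2")
        class_reports = {}
        for cname, spec in config.classify_contrasts.items():
            labels = classify.pool_labels(metadata, spec.get("pools", {}),
                                          keep=spec.get("keep"))
            table = classify.per_gene_accuracy(merged, labels, in_matrix,
                                               k_max=config.k_max, voting=config.voting,
                                               k_plain=config.k_plain)
            table.to_csv(outdir / f"per_gene_accuracy_{cname}.tsv", sep="\t", index=False)
            gene_set, result = classify.select_biomarker_set(
                table, merged, labels, k_max=config.k_max, voting=config.voting,
                k_plain=config.k_plain, strategy=config.selection_strategy)
            pd.DataFrame(result.per_sample,
                         columns=["sample_id", "true_label", "predicted_label"]).to_csv(
                outdir / f"jackknife_{cname}.tsv", sep="\t", index=False)
            class_reports[cname] = {
                "gene_set": gene_set,
                "accuracy_percent": result.accuracy_percent,
            }
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    report["stages"][name] = class_reports

    report["complete"] = True
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return report
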