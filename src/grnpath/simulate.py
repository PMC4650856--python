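"""Synthetic paired mRNA/miRNA expression data with planted structure.

The generator emulates the statistical structure the pipeline measures, with
full ground truth for every downstream stage:

* **True regulations** plant co-expression through a shared latent signal: a
  target with true regulator R has standardized latent
  ``u_t = s * alpha_true * u_R + sqrt(1 - alpha_true^2) * eps`` with
  ``s = -1`` for miRNA regulators (miRNAs repress their targets) and +1
  otherwise, so the expected Pearson correlation of a true edge is exactly
  ``+/- alpha_true``. Each target has at most one true regulator, keeping the
  per-edge correlation analytic. **Decoy** candidate edges carry no planted
  signal.
* **Seed genes** (default 26: 4 TFs, 7 miRNAs, 15 genes, the scale of a
  literature-curated disease gene list) are paired up through designated
  *plant-path* intermediate TFs: intermediate I_j regulates both members of
  seed pair j, so the shortest path between those seeds runs through I_j and
  the path stage has a known answer. Seeds beyond the paired ones stay
  unconnected — real seed lists also contain genes that fail to map.
* **DE genes** get a class-mean shift of ``de_log2fc`` (half up, half down) in
  the disease class versus normal; **biomarker genes** get a between-class
  shift of ``biomarker_shift`` for each diagnostic contrast.
* Everything else is i.i.d. Gaussian noise of sd ``noise_sd`` around a common
  baseline, on the log2 scale. Identical ``rng_seed`` gives bit-identical
  output.

Default class sizes copy a four-class pancreatic tumor study design
(14 SPN / 6 PanNET / 6 PDAC / 5 normal) so that leave-one-out behavior is
realistic at that scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .candidates import CandidateEdge
from .matrix import (ExpressionMatrix, write_expression_matrix,
                     write_feature_annotation, write_gene_list, write_sample_metadata)

__all__ = ["SyntheticConfig", "GroundTruth", "SimulatedDataset",
           "generate_regulations", "generate_expression", "generate_seed_list",
           "simulate", "write_dataset"]

#: Diagnostic contrasts with planted biomarkers: (name, positive class, rest).
BIOMARKER_CONTRASTS = ("SPN_vs_malignant", "SPN_vs_PanNET", "SPN_vs_PDAC")


def _default_classes() -> dict[str, int]:
    return {"SPN": 14, "PanNET": 6, "PDAC": 6, "normal": 5}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study-scale conditions."""

    n_per_class: dict = field(default_factory=_default_classes)
    n_genes: int = 150
    n_tfs: int = 30
    n_mirnas: int = 30
    regulation_density: float = 0.3   # candidate edges per eligible target
    decoy_fraction: float = 0.5       # fraction of candidate edges with no signal
    validated_fraction: float = 0.2   # fraction flagged experimentally validated
    alpha_true: float = 0.9           # planted Pearson correlation of true edges
    de_log2fc: float = 2.0            # class-mean shift of planted DE genes
    biomarker_shift: float = 3.0      # between-class shift of planted biomarkers
    noise_sd: float = 0.5             # log2-scale residual sd
    n_seed_tfs: int = 4
    n_seed_mirnas: int = 7
    n_seed_genes: int = 15
    n_plant_path: int = 5             # intermediate TFs planted on seed-pair paths
    n_de_genes: int = 10              # planted DE genes (disease vs normal)
    n_biomarkers_per_contrast: int = 5
    base_level: float = 8.0           # log2-scale baseline intensity
    rng_seed: int = 0

    @property
    def n_seeds(self) -> int:
        return self.n_seed_tfs + self.n_seed_mirnas + self.n_seed_genes

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_per_class.values()) or not self.n_per_class:
            raise ValueError("all class sizes must be positive")
        for name in ("n_genes", "n_tfs", "n_mirnas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("regulation_density", "decoy_fraction", "validated_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if not (0.0 < self.alpha_true < 1.0):
            raise ValueError("alpha_true must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_seed_tfs > self.n_tfs or self.n_seed_mirnas > self.n_mirnas \
                or self.n_seed_genes > self.n_genes:
            raise ValueError("seed counts exceed available features")
        if self.n_plant_path + self.n_seed_tfs > self.n_tfs:
            raise ValueError("not enough TFs for seeds plus plant-path intermediates")
        if 2 * self.n_plant_path > self.n_seeds:
            raise ValueError("not enough seeds to pair through the plant-path intermediates")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by feature id."""

    true_edges: list = field(default_factory=list)
    decoy_edges: list = field(default_factory=list)
    seed_genes: list = field(default_factory=list)
    plant_path_intermediates: list = field(default_factory=list)
    planted_pairs: list = field(default_factory=list)   # (seed_a, intermediate, seed_b)
    de_genes: dict = field(default_factory=dict)        # contrast -> {gene: direction}
    biomarker_genes: dict = field(default_factory=dict)  # contrast -> [genes]
    roles: dict = field(default_factory=dict)           # feature id -> role
    regulator_of: dict = field(default_factory=dict)    # target -> (regulator, sign)

    def to_json(self) -> str:
        payload = {
            "true_edges": [[e.regulator_id, e.target_id] for e in self.true_edges],
            "decoy_edges": [[e.regulator_id, e.target_id] for e in self.decoy_edges],
            "seed_genes": self.seed_genes,
            "plant_path_intermediates": self.plant_path_intermediates,
            "planted_pairs": self.planted_pairs,
            "de_genes": self.de_genes,
            "biomarker_genes": self.biomarker_genes,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SimulatedDataset:
    config: SyntheticConfig
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    metadata: pd.Series
    annotation: pd.Series
    candidate_edges: list
    ground_truth: GroundTruth
    seeds: list


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, cfg.rng_seed])


def generate_regulations(cfg: SyntheticConfig) -> tuple[list[CandidateEdge], GroundTruth]:
    """Plan features, seeds, planted paths, and the candidate edge set.

    Returns the full candidate list (true + decoy edges, each flagged
    predicted and possibly validated) and a GroundTruth whose edge, seed and
    planted-path fields are populated; expression-level fields (DE genes,
    biomarkers) are reserved here and shifted in :func:`generate_expression`.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    tfs = [f"TF{i:03d}" for i in range(1, cfg.n_tfs + 1)]
    mirnas = [f"MIR{i:03d}" for i in range(1, cfg.n_mirnas + 1)]
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    gt = GroundTruth()
    gt.roles = {**{t: "TF" for t in tfs}, **{m: "miRNA" for m in mirnas},
                **{g: "gene" for g in genes}}

    seed_tfs = [str(x) for x in rng.choice(tfs, size=cfg.n_seed_tfs, replace=False)]
    pool_tfs = [t for t in tfs if t not in seed_tfs]
    intermediates = [str(x) for x in rng.choice(pool_tfs, size=cfg.n_plant_path, replace=False)]
    seed_mirnas = [str(x) for x in rng.choice(mirnas, size=cfg.n_seed_mirnas, replace=False)]
    seed_genes = [str(x) for x in rng.choice(genes, size=cfg.n_seed_genes, replace=False)]
    seeds = seed_tfs + seed_mirnas + seed_genes
    gt.seed_genes = seeds
    gt.plant_path_intermediates = intermediates

    # reserve DE and biomarker genes among plain genes, disjoint from seeds
    free_genes = [g for g in genes if g not in seed_genes]
    n_reserved = cfg.n_de_genes + cfg.n_biomarkers_per_contrast * len(BIOMARKER_CONTRASTS)
    if n_reserved > len(free_genes):
        raise ValueError("not enough plain genes for DE and biomarker planting")
    reserved = [str(x) for x in rng.choice(free_genes, size=n_reserved, replace=False)]
    de_list = reserved[:cfg.n_de_genes]
    gt.de_genes = {"SPN_vs_normal": {
        g: ("up" if i % 2 == 0 else "down") for i, g in enumerate(de_list)}}
    offset = cfg.n_de_genes
    gt.biomarker_genes = {}
    for contrast in BIOMARKER_CONTRASTS:
        gt.biomarker_genes[contrast] = reserved[offset:offset + cfg.n_biomarkers_per_contrast]
        offset += cfg.n_biomarkers_per_contrast

    def true_edge(reg: str, tgt: str) -> CandidateEdge:
        sign = -1 if gt.roles[reg] == "miRNA" else 1
        gt.regulator_of[tgt] = (reg, sign)
        return CandidateEdge(reg, tgt, gt.roles[reg], gt.roles[tgt], frozenset({"predicted"}))

    edges: list[CandidateEdge] = []
    # planted seed-pair paths: intermediate I_j regulates both seeds of pair j
    pairing = [str(x) for x in rng.permutation(seeds)]
    for j, inter in enumerate(intermediates):
        a, b = pairing[2 * j], pairing[2 * j + 1]
        gt.planted_pairs.append([a, inter, b])
        edges.append(true_edge(inter, a))
        edges.append(true_edge(inter, b))

    # random true edges: eligible targets get exactly one regulator
    protected = set(seeds) | set(intermediates) | set(reserved)
    eligible_targets = [x for x in mirnas + genes if x not in protected]
    free_regs_tf = [t for t in tfs if t not in seed_tfs and t not in intermediates]
    free_regs_mir = [m for m in mirnas if m not in seed_mirnas]
    n_candidate = round(cfg.regulation_density * len(eligible_targets))
    if n_candidate == 0:
        raise ValueError("regulation_density implies zero candidate edges")
    n_true = round(n_candidate * (1.0 - cfg.decoy_fraction))
    n_decoy = n_candidate - n_true
    targets = [str(x) for x in rng.choice(eligible_targets,
                                          size=min(n_true, len(eligible_targets)),
                                          replace=False)]
    for tgt in targets:
        # miRNA targets take TF regulators only (miRNA->miRNA is out of model)
        pool = free_regs_tf if gt.roles[tgt] == "miRNA" else free_regs_tf + free_regs_mir
        if not pool:
            continue
        reg = pool[rng.integers(len(pool))]
        edges.append(true_edge(reg, tgt))
    gt.true_edges = list(edges)

    # decoys: admissible pairs with no planted signal, avoiding seeds and
    # intermediates so planted paths cannot be bypassed by chance
    existing = {(e.regulator_id, e.target_id) for e in edges}
    decoys: list[CandidateEdge] = []
    attempts = 0
    decoy_regs = free_regs_tf + free_regs_mir
    decoy_targets = eligible_targets
    if not decoy_regs or not decoy_targets:
        raise ValueError("no admissible regulators/targets for candidate edges")
    while len(decoys) < n_decoy and attempts < 100 * max(n_decoy, 1):
        attempts += 1
        reg = decoy_regs[rng.integers(len(decoy_regs))]
        tgt = decoy_targets[rng.integers(len(decoy_targets))]
        if reg == tgt or (reg, tgt) in existing:
            continue
        if gt.roles[reg] == "miRNA" and gt.roles[tgt] == "miRNA":
            continue
        existing.add((reg, tgt))
        decoys.append(CandidateEdge(reg, tgt, gt.roles[reg], gt.roles[tgt],
                                    frozenset({"predicted"})))
    gt.decoy_edges = decoys

    candidates = list(edges) + decoys
    # flag a fraction as experimentally validated (in addition to predicted)
    n_validated = round(cfg.validated_fraction * len(candidates))
    if n_validated:
        idx = rng.choice(len(candidates), size=n_validated, replace=False)
        for i in idx:
            e = candidates[i]
            candidates[i] = CandidateEdge(e.regulator_id, e.target_id, e.regulator_role,
                                          e.target_role, e.provenance | {"validated"})
    return candidates, gt


def generate_expression(
    cfg: SyntheticConfig, ground_truth: GroundTruth
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.Series]:
    """Draw the paired log2 expression matrices and sample metadata."""
    cfg.validate()
    rng = _rng(cfg, 2)
    gt = ground_truth
    sample_ids: list[str] = []
    sample_class: list[str] = []
    for label, n in cfg.n_per_class.items():
        for i in range(1, n + 1):
            sample_ids.append(f"{label}_{i:02d}")
            sample_class.append(label)
    meta = pd.Series(sample_class, index=pd.Index(sample_ids, name="sample_id"),
                     name="class_label")
    n_samples = len(sample_ids)
    is_class = {lab: np.array([c == lab for c in sample_class]) for lab in cfg.n_per_class}

    # standardized latent signals in dependency order (chains are short: TF ->
    # miRNA -> gene at most, plus intermediate-TF -> seed-TF)
    latent: dict[str, np.ndarray] = {}
    pending = list(gt.roles)
    a = cfg.alpha_true
    while pending:
        progressed = False
        rest = []
        for fid in pending:
            reg_sign = gt.regulator_of.get(fid)
            if reg_sign is None:
                latent[fid] = rng.standard_normal(n_samples)
                progressed = True
            elif reg_sign[0] in latent:
                reg, sign = reg_sign
                eps = rng.standard_normal(n_samples)
                latent[fid] = sign * a * latent[reg] + np.sqrt(1 - a * a) * eps
                progressed = True
            else:
                rest.append(fid)
        pending = rest
        if not progressed:
            raise RuntimeError("cycle in planted regulations")  # pragma: no cover

    values = {fid: cfg.base_level + cfg.noise_sd * latent[fid] for fid in gt.roles}

    # planted DE genes: disease-class shift versus everything else; planting
    # is a no-op for class labels absent from this run's design
    for contrast, gene_dirs in gt.de_genes.items():
        disease = contrast.split("_vs_")[0]
        if disease not in is_class:
            continue
        for gene, direction in gene_dirs.items():
            shift = cfg.de_log2fc if direction == "up" else -cfg.de_log2fc
            values[gene] = values[gene] + shift * is_class[disease]

    # planted biomarkers: shift the non-SPN side of each diagnostic contrast,
    # except the pooled-malignant contrast which shifts SPN itself
    contrast_shift = {
        "SPN_vs_malignant": ("SPN", +1.0),
        "SPN_vs_PanNET": ("PanNET", -1.0),
        "SPN_vs_PDAC": ("PDAC", -1.0),
    }
    for contrast, genes in gt.biomarker_genes.items():
        label, sgn = contrast_shift[contrast]
        if label not in is_class:
            continue
        for gene in genes:
            values[gene] = values[gene] + sgn * cfg.biomarker_shift * is_class[label]

    mrna_ids = [f for f, r in gt.roles.items() if r in ("TF", "gene")]
    mirna_ids = [f for f, r in gt.roles.items() if r == "miRNA"]
    mrna = ExpressionMatrix(pd.DataFrame(
        [values[f] for f in mrna_ids], index=mrna_ids, columns=sample_ids), scale="log2")
    mirna = ExpressionMatrix(pd.DataFrame(
        [values[f] for f in mirna_ids], index=mirna_ids, columns=sample_ids), scale="log2")
    return mrna, mirna, meta


def generate_seed_list(cfg: SyntheticConfig, ground_truth: GroundTruth) -> list[str]:
    """The planted seed list (default 26 ids: 4 TFs, 7 miRNAs, 15 genes)."""
    if not ground_truth.seed_genes:
        raise ValueError("ground truth has no seeds; run generate_regulations first")
    return list(ground_truth.seed_genes)


def simulate(cfg: SyntheticConfig | None = None) -> SimulatedDataset:
    """Run the full generator: regulations, expression, seeds."""
    cfg = cfg or SyntheticConfig()
    candidates, gt = generate_regulations(cfg)
    mrna, mirna, meta = generate_expression(cfg, gt)
    seeds = generate_seed_list(cfg, gt)
    annotation = pd.Series(gt.roles, name="role").rename_axis("feature_id")
    return SimulatedDataset(cfg, mrna, mirna, meta, annotation, candidates, gt, seeds)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all standard pipeline inputs plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "mrna": outdir / "mrna.tsv",
        "mirna": outdir / "mirna.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotation": outdir / "annotation.tsv",
        "edges_predicted": outdir / "edges_predicted.tsv",
        "edges_validated": outdir / "edges_validated.tsv",
        "seeds": outdir / "seeds.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_expression_matrix(ds.mrna, files["mrna"])
    write_expression_matrix(ds.mirna, files["mirna"])
    write_sample_metadata(ds.metadata, files["metadata"])
    write_feature_annotation(ds.annotation, files["annotation"])
    predicted = [e for e in ds.candidate_edges if "predicted" in e.provenance]
    validated = [e for e in ds.candidate_edges if "validated" in e.provenance]
    for key, edges in (("edges_predicted", predicted), ("edges_validated", validated)):
        with open(files[key], "w", encoding="utf-8") as fh:
            for e in edges:
                fh.write(f"{e.regulator_id}\t{e.target_id}\n")
    write_gene_list(ds.seeds, files["seeds"])
    files["ground_truth"].write_text(ds.ground_truth.to_json(), encoding="utf-8")
    return files
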