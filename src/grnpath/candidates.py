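"""Candidate regulatory network assembly.

Candidate edges come from target-prediction and curated-interaction resources
(e.g. sequence-based TF/miRNA target prediction and experimentally validated
regulation databases). This module loads plain 2-column edge lists tagged with
a provenance flag, attaches regulator/target roles from the feature annotation,
drops edges the model does not admit, and merges everything into a deduplicated
candidate network.

Admissible edge categories are the three the regulatory model counts:
TF->gene, TF->miRNA and miRNA->gene. TFs are protein-coding, so a miRNA
regulating a TF is a miRNA->gene edge; miRNA->miRNA regulation is rejected as
out of model. Self-loops are removed because they break path semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .matrix import ParseError

logger = logging.getLogger("grnpath")

__all__ = ["CandidateEdge", "CandidateNetwork", "load_edges", "merge", "edge_category"]

PROVENANCES = ("predicted", "validated")
CATEGORIES = ("TF->gene", "TF->miRNA", "miRNA->gene")


@dataclass(frozen=True)
class CandidateEdge:
    """One directed candidate regulation with provenance."""

    regulator_id: str
    target_id: str
    regulator_role: str  # "TF" or "miRNA"
    target_role: str     # "TF", "miRNA" or "gene"
    provenance: frozenset = field(default_factory=frozenset)

    @property
    def category(self) -> str:
        return edge_category(self.regulator_role, self.target_role)

    @property
    def key(self) -> tuple[str, str]:
        return (self.regulator_id, self.target_id)


def edge_category(regulator_role: str, target_role: str) -> str:
    """Map endpoint roles to one of the three admissible edge categories."""
    if regulator_role == "TF":
        return "TF->miRNA" if target_role == "miRNA" else "TF->gene"
    if regulator_role == "miRNA":
        if target_role == "miRNA":
            raise ValueError("miRNA->miRNA regulation is out of model")
        return "miRNA->gene"
    raise ValueError(f"regulator role must be TF or miRNA, got {regulator_role!r}")


@dataclass
class CandidateNetwork:
    """Deduplicated candidate edge set plus bookkeeping counts."""

    edges: list[CandidateEdge]
    category_counts: dict[str, int]
    n_validated: int

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": e.regulator_id,
                "target": e.target_id,
                "category": e.category,
                "provenance": ",".join(sorted(e.provenance)),
            }
            for e in self.edges
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "category", "provenance"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_edges(
    paths_with_provenance: Sequence[tuple[str | Path, str]],
    annotation: pd.Series,
) -> list[CandidateEdge]:
    """Load 2-column (regulator, target) TSVs, attaching roles and provenance.

    Edges whose endpoints are missing from the annotation, self-loops, edges
    with a non-regulator on the left and miRNA->miRNA edges are dropped; each
    drop class is counted and logged.
    """
    edges: list[CandidateEdge] = []
    for path, provenance in paths_with_provenance:
        if provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}, got {provenance!r}")
        n_kept = n_unknown = n_invalid = n_self = 0
        path = Path(path)
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            reg, tgt = parts
            if reg == tgt:
                n_self += 1
                continue
            if reg not in annotation.index or tgt not in annotation.index:
                n_unknown += 1
                continue
            reg_role, tgt_role = annotation[reg], annotation[tgt]
            if reg_role not in ("TF", "miRNA") or (reg_role == "miRNA" and tgt_role == "miRNA"):
                n_invalid += 1
                continue
            edges.append(CandidateEdge(reg, tgt, reg_role, tgt_role, frozenset({provenance})))
            n_kept += 1
        if n_kept == 0:
            logger.warning("edge file %s (%s): no usable edges", path, provenance)
        logger.info(
            "edge file %s (%s): kept %d, dropped %d unknown-id, %d invalid-role, %d self-loop",
            path, provenance, n_kept, n_unknown, n_invalid, n_self)
    return edges


def merge(edge_lists: Iterable[Iterable[CandidateEdge]]) -> CandidateNetwork:
    """Union of edge lists; duplicate (regulator, target) pairs merge provenance.

    Idempotent and order-independent: the result is sorted by (regulator, target)
    and each pair's provenance is the union over all occurrences.
    """
    merged: dict[tuple[str, str], CandidateEdge] = {}
    for edges in edge_lists:
        for e in edges:
            prior = merged.get(e.key)
            if prior is None:
                merged[e.key] = e
            else:
                if (prior.regulator_role, prior.target_role) != (e.regulator_role, e.target_role):
                    raise ValueError(f"conflicting roles for edge {e.key}")
                merged[e.key] = replace(prior, provenance=prior.provenance | e.provenance)
    edges_sorted = [merged[k] for k in sorted(merged)]
    counts = {c: 0 for c in CATEGORIES}
    n_validated = 0
    for e in edges_sorted:
        counts[e.category] += 1
        if "validated" in e.provenance:
            n_validated += 1
    return CandidateNetwork(edges_sorted, counts, n_validated)
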