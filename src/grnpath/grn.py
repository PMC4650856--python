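"""Weighted gene regulatory network construction.

Candidate edges are scored by the Pearson correlation alpha of the regulator
and target expression vectors over a chosen sample subset (by default the
disease-class samples, making the network tissue-specific). The co-expression
cutoff on |alpha| is chosen by how well the degree distribution of the
thresholded network fits a power law p(k) = k^-lambda — the scale-free
criterion: the fit is a least-squares line of log10 p(k) on log10 k over the
distinct observed degrees, lambda_hat is minus the slope and the fitness is
the R^2 of that line. Retained edges carry the path weight

    beta = 1 - |alpha|

so that strongly co-expressed regulations are short in the path metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .candidates import CandidateEdge, CATEGORIES
from .matrix import ExpressionMatrix

logger = logging.getLogger("grnpath")

__all__ = [
    "ScoredEdge",
    "GRNEdge",
    "GRN",
    "PowerLawFitError",
    "score_edges",
    "fit_power_law",
    "degree_histogram",
    "scan_cutoffs",
    "build_grn",
]


class PowerLawFitError(ValueError):
    """Raised when a degree distribution has too few distinct degrees to fit."""


@dataclass(frozen=True)
class ScoredEdge:
    """A candidate edge with its Pearson co-expression alpha."""

    regulator_id: str
    target_id: str
    regulator_role: str
    target_role: str
    provenance: frozenset
    alpha: float

    @property
    def category(self) -> str:
        from .candidates import edge_category

        return edge_category(self.regulator_role, self.target_role)


@dataclass(frozen=True)
class GRNEdge:
    """A retained regulation: |alpha| >= cutoff, beta = 1 - |alpha|."""

    regulator_id: str
    target_id: str
    regulator_role: str
    target_role: str
    provenance: frozenset
    alpha: float
    beta: float

    @property
    def category(self) -> str:
        from .candidates import edge_category

        return edge_category(self.regulator_role, self.target_role)


@dataclass
class GRN:
    """The thresholded, weighted regulatory network."""

    edges: list[GRNEdge]
    cutoff_tf: float
    cutoff_mirna: float

    @property
    def nodes(self) -> dict[str, str]:
        """Node id -> role, over all edge endpoints."""
        roles: dict[str, str] = {}
        for e in self.edges:
            roles[e.regulator_id] = e.regulator_role
            roles[e.target_id] = roles.get(e.target_id, e.target_role)
        # a node that ever acts as regulator keeps its regulator role
        for e in self.edges:
            roles[e.regulator_id] = e.regulator_role
        return roles

    def summary(self) -> dict:
        counts = {c: 0 for c in CATEGORIES}
        n_validated = 0
        for e in self.edges:
            counts[e.category] += 1
            if "validated" in e.provenance:
                n_validated += 1
        roles = self.nodes
        role_counts = {r: sum(1 for v in roles.values() if v == r) for r in ("TF", "miRNA", "gene")}
        return {
            "n_nodes": len(roles),
            "n_edges": len(self.edges),
            "node_roles": role_counts,
            "category_counts": counts,
            "n_validated": n_validated,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": e.regulator_id,
                "target": e.target_id,
                "category": e.category,
                "alpha": e.alpha,
                "beta": e.beta,
                "validated": "validated" in e.provenance,
            }
            for e in self.edges
        ]
        return pd.DataFrame(
            rows, columns=["regulator", "target", "category", "alpha", "beta", "validated"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _locate(feature_id: str, mrna: ExpressionMatrix, mirna: ExpressionMatrix) -> pd.Series:
    if feature_id in mirna.values.index:
        return mirna.values.loc[feature_id]
    if feature_id in mrna.values.index:
        return mrna.values.loc[feature_id]
    raise KeyError(f"feature {feature_id!r} absent from both matrices")


def score_edges(
    candidates: Iterable[CandidateEdge],
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    sample_subset: Sequence[str] | None = None,
) -> list[ScoredEdge]:
    """Attach Pearson alpha to every candidate edge.

    Correlations are computed over ``sample_subset`` restricted to the samples
    present in both matrices (regulator and target may live on different
    platforms). Edges with a constant expression vector are dropped and logged.
    """
    common = [s for s in mrna.sample_ids if s in set(mirna.sample_ids)]
    if sample_subset is not None:
        subset = set(sample_subset)
        common = [s for s in common if s in subset]
    if len(common) < 3:
        raise ValueError(f"need >= 3 shared samples for correlation, have {len(common)}")
    scored: list[ScoredEdge] = []
    n_constant = 0
    for e in candidates:
        x = _locate(e.regulator_id, mrna, mirna)[common].to_numpy(dtype=float)
        y = _locate(e.target_id, mrna, mirna)[common].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            n_constant += 1
            continue
        alpha = float(np.corrcoef(x, y)[0, 1])
        scored.append(ScoredEdge(e.regulator_id, e.target_id, e.regulator_role,
                                 e.target_role, e.provenance, alpha))
    if n_constant:
        logger.info("score_edges: dropped %d edges with constant expression", n_constant)
    return scored


def degree_histogram(degrees: Iterable[int]) -> dict[int, int]:
    """Frequency of each degree k >= 1 (k = 0 nodes carry no information here)."""
    hist: dict[int, int] = {}
    for k in degrees:
        if k >= 1:
            hist[k] = hist.get(k, 0) + 1
    return hist


def fit_power_law(histogram: Mapping[int, int]) -> tuple[float, float]:
    """Least-squares power-law fit of a degree histogram.

    p(k) is the empirical fraction of nodes with degree k; the fit is a line
    through (log10 k, log10 p(k)) over degrees with nonzero frequency.

    Returns
    -------
    (lambda_hat, r_squared)
        lambda_hat = -slope of the fit; r_squared its coefficient of
        determination.

    Raises
    ------
    PowerLawFitError
        If fewer than 3 distinct degrees have nonzero frequency.
    """
    ks = np.array(sorted(k for k, n in histogram.items() if n > 0 and k >= 1), dtype=float)
    if ks.size < 3:
        raise PowerLawFitError(
            f"power-law fit needs >= 3 distinct degrees, got {ks.size}")
    counts = np.array([histogram[int(k)] for k in ks], dtype=float)
    p = counts / counts.sum()
    res = stats.linregress(np.log10(ks), np.log10(p))
    return -float(res.slope), float(res.rvalue) ** 2


def scan_cutoffs(
    scored: Sequence[ScoredEdge],
    grid: Sequence[float],
) -> pd.DataFrame:
    """Power-law fitness of each sub-network over a grid of |alpha| cutoffs.

    For every cutoff, the miRNA-regulator and TF-regulator sub-networks are
    thresholded separately and both their in-degree (targets) and out-degree
    (regulators) distributions are fit. Undefined fits (too few distinct
    degrees) are flagged with ``fit_ok = False`` and NaN estimates rather than
    excluded, so the scan table always covers the full grid.
    """
    for c in grid:
        if not (0.0 <= c < 1.0):
            raise ValueError(f"cutoffs must lie in [0, 1), got {c}")
    rows = []
    for cutoff in grid:
        for role, name in (("miRNA", "miRNA_regulator"), ("TF", "TF_regulator")):
            sub = [e for e in scored if e.regulator_role == role and abs(e.alpha) >= cutoff]
            targets: dict[str, int] = {}
            regulators: dict[str, int] = {}
            for e in sub:
                targets[e.target_id] = targets.get(e.target_id, 0) + 1
                regulators[e.regulator_id] = regulators.get(e.regulator_id, 0) + 1
            for direction, degs in (("in_degree", targets), ("out_degree", regulators)):
                try:
                    lam, r2 = fit_power_law(degree_histogram(degs.values()))
                    ok = True
                except PowerLawFitError:
                    lam, r2, ok = float("nan"), float("nan"), False
                rows.append({
                    "cutoff": cutoff,
                    "subnetwork": name,
                    "direction": direction,
                    "lambda_hat": lam,
                    "r_squared": r2,
                    "n_edges": len(sub),
                    "n_targets": len(targets),
                    "n_regulators": len(regulators),
                    "fit_ok": ok,
                })
    return pd.DataFrame(rows)


def build_grn(
    scored: Sequence[ScoredEdge],
    cutoff_tf: float = 0.8,
    cutoff_mirna: float = 0.8,
) -> GRN:
    """Retain edges with |alpha| >= the cutoff of their regulator class.

    The default cutoff 0.8 for both classes balances scale-free fitness
    against network size. Ties at the cutoff are retained.
    """
    for c in (cutoff_tf, cutoff_mirna):
        if not (0.0 <= c < 1.0):
            raise ValueError(f"cutoff must lie in [0, 1), got {c}")
    edges = []
    for e in scored:
        cutoff = cutoff_tf if e.regulator_role == "TF" else cutoff_mirna
        if abs(e.alpha) >= cutoff:
            edges.append(GRNEdge(e.regulator_id, e.target_id, e.regulator_role,
                                 e.target_role, e.provenance, e.alpha, 1.0 - abs(e.alpha)))
    if not edges:
        logger.warning("build_grn: no edges survive cutoffs (tf=%s, mirna=%s)",
                       cutoff_tf, cutoff_mirna)
    return GRN(edges, cutoff_tf=cutoff_tf, cutoff_mirna=cutoff_mirna)
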