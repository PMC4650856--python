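"""Expression matrices, sample metadata and feature annotation.

The central container is :class:`ExpressionMatrix`: a features x samples table
of microarray intensities, either on the raw linear scale or log2-transformed.
All downstream stages (correlation scoring, differential expression, KNN
classification) consume log2 values.

File formats are deliberately plain: tab-separated text with a header row of
sample ids and a first column of feature ids, UTF-8, '.' decimal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ParseError",
    "FEATURE_ROLES",
    "CLASS_LABELS",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_feature_annotation",
    "write_feature_annotation",
    "read_gene_list",
    "write_gene_list",
]

#: Node roles of the regulatory network: transcription factors, microRNAs and
#: plain (non-TF) protein-coding genes.
FEATURE_ROLES = ("TF", "miRNA", "gene")

#: The study's four sample classes; arbitrary label sets are accepted everywhere,
#: these are only the defaults the simulator emits.
CLASS_LABELS = ("SPN", "PanNET", "PDAC", "normal")


class ParseError(ValueError):
    """Raised when an input file violates the expected tabular format."""


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of expression intensities.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
    scale
        Either ``"raw"`` (linear intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dupes}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression values must be numeric")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values; "
                             "missing values are not supported")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.values[ids], scale=self.scale)

    def vector(self, feature_id: str) -> pd.Series:
        """Expression of one feature across samples."""
        return self.values.loc[feature_id]


def read_expression_matrix(path: str | Path, scale_hint: str = "log2") -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature ids, header sample ids).

    Errors name the offending 1-based line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}:1: empty or missing header row")
        cols = header.rstrip("\n").split("\t")
        sample_ids = cols[1:]
        if not sample_ids:
            raise ParseError(f"{path}:1: header has no sample columns")
        if len(set(sample_ids)) != len(sample_ids):
            raise ParseError(f"{path}:1: duplicate sample ids in header")
        n_cols = len(sample_ids)
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols + 1} columns, got {len(parts)}")
            fid = parts[0]
            if fid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            seen.add(fid)
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            feature_ids.append(fid)
    frame = pd.DataFrame(rows, index=feature_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(frame, scale=scale_hint)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV that :func:`read_expression_matrix` round-trips exactly."""
    buf = io.StringIO()
    m.values.to_csv(buf, sep="\t", index_label="feature_id")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_sample_metadata(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (sample_id, class_label) into a Series keyed by sample."""
    frame = _read_two_column(path, ("sample_id", "class_label"))
    meta = frame.set_index("sample_id")["class_label"]
    if meta.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids in metadata")
    return meta


def write_sample_metadata(meta: pd.Series, path: str | Path) -> None:
    frame = meta.rename("class_label").rename_axis("sample_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_feature_annotation(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (feature_id, role) mapping features to TF/miRNA/gene."""
    frame = _read_two_column(path, ("feature_id", "role"))
    bad = frame[~frame["role"].isin(FEATURE_ROLES)]
    if not bad.empty:
        raise ParseError(
            f"{path}: invalid roles {sorted(bad['role'].unique())}; "
            f"expected one of {FEATURE_ROLES}")
    ann = frame.set_index("feature_id")["role"]
    if ann.index.has_duplicates:
        raise ParseError(f"{path}: duplicate feature ids in annotation")
    return ann


def write_feature_annotation(annotation: pd.Series, path: str | Path) -> None:
    frame = annotation.rename("role").rename_axis("feature_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One feature id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{x}\n" for x in ids), encoding="utf-8")


def _read_two_column(path: str | Path, expected_header: tuple[str, str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: unreadable TSV ({exc})") from exc
    if list(frame.columns) != list(expected_header):
        raise ParseError(
            f"{path}:1: expected header {expected_header}, got {tuple(frame.columns)}")
    if frame.isna().any().any():
        raise ParseError(f"{path}: empty cells are not allowed")
    return frame


def class_groups(meta: pd.Series) -> dict[str, list[str]]:
    """Samples per class label, in metadata order."""
    groups: dict[str, list[str]] = {}
    for sample, label in meta.items():
        groups.setdefault(label, []).append(sample)
    return groups
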