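"""Readers and writers for the tabular formats the pipeline consumes.

Supported formats
-----------------
GMT
    Broad-style gene-set format: one set per line,
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.
RNK
    Two-column tab-delimited ranked list (identifier, score).
Matrix TSV
    Tab-delimited numeric matrix, first column feature (probe) identifiers,
    header row of sample identifiers.
Design TSV
    Sample sheet with at least the columns ``sample_id``, ``subset``,
    ``donor``; one row per array/sample.

All files are UTF-8 with ``.`` as the decimal separator.  Readers never
reorder rows or columns; ranked lists are the single exception, where the
container itself enforces descending-score order (ties broken by identifier
so the order is reproducible across platforms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "RankedList",
    "FormatError",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "validate_design",
]

DESIGN_COLUMNS = ("sample_id", "subset", "donor")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene (or probe) identifiers.

    Duplicate members are collapsed on construction, keeping first
    occurrence order, so ``genes`` behaves as an ordered set.
    """

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        # empty sets are legal in memory (a derivation can come up empty)
        # but cannot be written to GMT
        object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class RankedList:
    """Identifiers ordered by strictly descending score.

    Ties in score are broken by identifier (lexicographic, ascending) so
    that the rank order is deterministic regardless of input order.
    """

    ids: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Series(self.ids).value_counts()
            dupes = list(dupes[dupes > 1].index[:5])
            raise ValueError(f"duplicate identifiers in ranked list: {dupes}")
        order = sorted(
            range(len(self.ids)), key=lambda i: (-self.scores[i], self.ids[i])
        )
        object.__setattr__(self, "ids", tuple(self.ids[i] for i in order))
        object.__setattr__(
            self, "scores", tuple(float(self.scores[i]) for i in order)
        )

    @classmethod
    def from_series(cls, series: pd.Series) -> "RankedList":
        return cls(tuple(str(i) for i in series.index), tuple(series.values))

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.ids), dtype=float)

    def score_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file into a list of :class:`GeneSet`.

    Each non-blank line must have at least three tab-separated fields
    (name, description, one or more genes).  Duplicate genes within a
    line are collapsed; gene order is preserved.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            genes = tuple(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(
                    f"{path}: line {lineno}: gene set {fields[0]!r} is empty"
                )
            sets.append(GeneSet(fields[0], fields[1], genes))
    return sets


def write_gmt(genesets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in genesets:
            if not gs.genes:
                raise ValueError(
                    f"cannot write empty GeneSet {gs.name!r} to GMT"
                )
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# RNK

def read_rnk(path: str | Path) -> RankedList:
    """Read a two-column RNK file; lines starting with '#' are skipped."""
    ids: list[str] = []
    scores: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 columns, got "
                    f"{len(fields)}"
                )
            try:
                score = float(fields[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric score "
                    f"{fields[1]!r}"
                ) from exc
            ids.append(fields[0])
            scores.append(score)
    return RankedList(tuple(ids), tuple(scores))


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ident, score in zip(ranked.ids, ranked.scores):
            fh.write(f"{ident}\t{score:.10g}\n")


# ---------------------------------------------------------------------------
# Matrix TSV

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples numeric matrix.

    First column holds probe identifiers; the header row holds sample
    identifiers.  Duplicate probe or sample identifiers and non-numeric
    cells are format errors (the error message names the offending
    coordinates).  Row and column order are preserved as-is.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_cols = pd.Index(header)[pd.Index(header).duplicated()]
    if len(dup_cols):
        raise FormatError(
            f"{path}: duplicate sample identifiers: {dup_cols[:5].tolist()}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][:5].tolist()
        raise FormatError(f"{path}: duplicate probe identifiers: {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise FormatError(
            f"{path}: non-numeric cell at probe {df.index[r]!r}, sample "
            f"{df.columns[c]!r}: {df.iloc[r, c]!r}"
        )
    return numeric.astype(float)


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str = "probe_id") -> None:
    out = matrix.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Sample design

def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet for the pipeline's structural requirements.

    Requires ``sample_id``, ``subset``, ``donor`` columns, unique sample
    identifiers and unique (subset, donor) pairs — each donor contributes
    at most one array per subset, which is what the paired comparisons
    downstream rely on.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"design is missing columns: {missing}")
    design = design.copy()
    for col in DESIGN_COLUMNS:
        design[col] = design[col].astype(str)
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"]
        raise FormatError(f"duplicate sample_id in design: {dup.tolist()[:5]}")
    pairs = design[["subset", "donor"]]
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].apply(tuple, axis=1).tolist()[:5]
        raise FormatError(f"duplicate (subset, donor) pairs in design: {dup}")
    return design


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    return validate_design(design)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    validate_design(design).to_csv(path, sep="\t", index=False)
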