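"""Expression-matrix preprocessing and unsupervised structure analysis.

The module operates on :class:`ExpressionStudy` objects: a probes x samples
log2 expression matrix, a probe-to-gene map, and a sample design
(subset/donor labels).  It provides quantile normalization, the strict
variance filter used to select informative probes, hierarchical clustering
of samples with bootstrap support values (Pearson correlation distance,
Ward.D2 linkage), and PCA of the probe-centered data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io_formats import validate_design

__all__ = [
    "ExpressionStudy",
    "Dendrogram",
    "quantile_normalize",
    "variance_filter",
    "bootstrap_cluster",
    "pca",
]


@dataclass
class ExpressionStudy:
    """Log2 expression values with probe and sample annotation.

    Parameters
    ----------
    values
        probes x samples matrix of log2 expression values.
    probe_to_gene
        Series mapping probe identifier to gene symbol.  Probes missing
        from the map are flagged (kept, with gene ``""``).
    design
        Sample sheet with columns ``sample_id``, ``subset``, ``donor``;
        every sample must appear exactly once as a matrix column.
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.design = validate_design(self.design)
        cols = list(self.values.columns)
        ids = list(self.design["sample_id"])
        if sorted(cols) != sorted(ids):
            raise ValueError(
                "design sample_ids do not match matrix columns: "
                f"{sorted(set(cols) ^ set(ids))[:5]}"
            )
        # align design row order to column order
        self.design = (
            self.design.set_index("sample_id").loc[cols].reset_index()
        )
        self.probe_to_gene = self.probe_to_gene.reindex(
            self.values.index
        ).fillna("")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of(self, subset: str) -> list[str]:
        """Sample ids belonging to one subset, in column order."""
        sel = self.design.loc[self.design["subset"] == subset, "sample_id"]
        if sel.empty:
            raise KeyError(f"unknown subset label: {subset!r}")
        return sel.tolist()

    def gene_count(self) -> int:
        genes = set(self.probe_to_gene.values) - {""}
        return len(genes)


@dataclass
class Dendrogram:
    """Sample dendrogram with per-node bootstrap probabilities.

    ``support`` maps each internal node's leaf set (a frozenset of sample
    ids) to its bootstrap probability: the fraction of probe-resampled
    replicate trees containing the identical cluster.
    """

    labels: tuple[str, ...]
    merge: np.ndarray  # scipy linkage matrix
    support: dict[frozenset, float] = field(default_factory=dict)

    def clusters(self) -> list[frozenset]:
        return _linkage_clusters(self.merge, self.labels)

    def to_newick(self) -> str:
        """Newick string with bootstrap probabilities as internal labels."""
        n = len(self.labels)
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        members: dict[int, frozenset] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        for k, (a, b, h, _) in enumerate(self.merge):
            a, b = int(a), int(b)
            node_id = n + k
            members[node_id] = members[a] | members[b]
            bp = self.support.get(members[node_id], float("nan"))
            label = f"{bp:.3f}" if bp == bp else ""
            nodes[node_id] = f"({nodes[a]},{nodes[b]}){label}:{h:.6g}"
        return nodes[n + len(self.merge) - 1] + ";"


def quantile_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common mean quantile distribution.

    The reference distribution is the row-wise mean of the column-sorted
    matrix.  Each value is replaced by the reference value at its rank
    within its column; tied values receive the mean of the reference
    values at the rank positions they jointly occupy.
    """
    if raw.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    x = raw.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite values")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        by_rank = np.empty_like(ref)
        by_rank[order] = ref
        # average reference values over tied observations
        out[:, j] = (
            pd.Series(by_rank).groupby(pd.Series(col), sort=False)
            .transform("mean").to_numpy()
        )
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def variance_filter(
    study: ExpressionStudy, threshold: float = 0.01
) -> ExpressionStudy:
    """Retain probes whose across-sample variance strictly exceeds ``threshold``.

    Variance uses the unbiased (n-1) denominator on the log2 values.  The
    filtered study's report is available via :meth:`ExpressionStudy.gene_count`
    and ``n_probes``.
    """
    if threshold < 0:
        raise ValueError("variance threshold must be >= 0")
    var = study.values.var(axis=1, ddof=1)
    keep = var > threshold
    return replace(
        study,
        values=study.values.loc[keep],
        probe_to_gene=study.probe_to_gene.loc[keep],
        design=study.design.copy(),
    )


def _pearson_distance(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson correlation between sample columns."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    return squareform(dist, checks=False)


def _linkage_clusters(merge: np.ndarray, labels: tuple[str, ...]) -> list[frozenset]:
    """Leaf sets of all internal nodes of a scipy linkage matrix."""
    n = len(labels)
    members: dict[int, frozenset] = {
        i: frozenset([labels[i]]) for i in range(n)
    }
    out = []
    for k, row in enumerate(merge):
        a, b = int(row[0]), int(row[1])
        members[n + k] = members[a] | members[b]
        out.append(members[n + k])
    return out


def bootstrap_cluster(
    study: ExpressionStudy,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> Dendrogram:
    """Hierarchical clustering of samples with bootstrap support.

    Samples are clustered on 1 - Pearson correlation of their probe
    profiles with Ward.D2 linkage (the Lance-Williams update on squared
    dissimilarities, as implemented by :func:`scipy.cluster.hierarchy.linkage`
    with ``method="ward"`` on a precomputed distance).  Support for each
    internal node is the plain bootstrap probability: the fraction of
    ``n_boot`` probe resamples (with replacement, original size) whose
    tree contains the identical sample cluster.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = study.values.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("clustering needs >= 3 samples")
    if x.shape[0] < 2:
        raise ValueError("clustering needs >= 2 probes")
    labels = tuple(study.values.columns)
    merge = linkage(_pearson_distance(x), method="ward")
    observed = _linkage_clusters(merge, labels)
    counts = {cl: 0 for cl in observed}
    rng = np.random.default_rng(seed)
    n_probes = x.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_probes, size=n_probes)
        rep_merge = linkage(_pearson_distance(x[idx]), method="ward")
        rep = set(_linkage_clusters(rep_merge, labels))
        for cl in counts:
            if cl in rep:
                counts[cl] += 1
    support = {cl: counts[cl] / n_boot for cl in counts}
    return Dendrogram(labels=labels, merge=merge, support=support)


def pca(study: ExpressionStudy) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the probe-centered expression matrix.

    Returns ``(scores, explained_variance_ratio)`` where ``scores`` is a
    samples x components frame of principal-component coordinates.
    Components are ordered by non-increasing explained variance and score
    columns are mutually orthogonal.
    """
    if study.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    x = study.values.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)  # per-probe centering
    # samples as observations
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    n_comp = min(study.n_samples, study.n_probes)
    scores = u[:, :n_comp] * s[:n_comp]
    total = (s**2).sum()
    ratio = (s[:n_comp] ** 2 / total) if total > 0 else np.zeros(n_comp)
    frame = pd.DataFrame(
        scores,
        index=study.values.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return frame, ratio
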