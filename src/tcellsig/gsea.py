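"""Gene set enrichment analysis with a gene-set permutation null.

The engine implements weighted Kolmogorov–Smirnov enrichment scoring over a
ranked identifier list: walking the list from top to bottom, members of the
set ("hits") increment a running sum by their |score|^p weight normalized by
the weight sum over set members, non-members decrement it by 1/(N - N_hit),
and the enrichment score (ES) is the signed maximum deviation of the running
sum from zero.

Significance comes from a gene-set (identifier) permutation null: for a set
of size k, ``n_perm`` random k-subsets of the ranked universe are scored.
The nominal p-value is the same-sign tail fraction of that null, the
normalized enrichment score (NES) divides the observed ES by the mean
magnitude of same-sign null ES values, and the FDR compares each observed
NES against the pooled, per-set-normalized permutation NES distribution,
stratified by sign and capped at 1.

Two entry points cover the two use modes: :func:`gsea_run` ranks genes
itself from a two-class expression study using the difference-of-classes
metric (the natural metric for log2 data, where a difference is a log fold
change), while :func:`gsea_preranked` takes a caller-supplied ranked list.

The permutation stream for each gene set is keyed on ``(seed, set index)``,
so results are bitwise reproducible and independent of evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionStudy
from .io_formats import GeneSet, RankedList

__all__ = [
    "GseaConfig",
    "EnrichmentResult",
    "rank_by_metric",
    "enrichment_score",
    "gsea_run",
    "gsea_preranked",
    "nondifferential_geneset",
]


@dataclass(frozen=True)
class GseaConfig:
    n_perm: int = 1000
    weight_exponent: float = 1.0
    fdr_threshold: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")


@dataclass
class EnrichmentResult:
    geneset_name: str
    es: float
    nes: float
    nominal_p: float
    fdr: float
    size: int
    leading_edge: tuple[str, ...] = ()
    running_profile: np.ndarray | None = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return self.fdr < 0.25


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per gene set)."""
    return pd.DataFrame(
        {
            "geneset": [r.geneset_name for r in results],
            "size": [r.size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "nominal_p": [r.nominal_p for r in results],
            "fdr": [r.fdr for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Ranking metric

def collapse_probes(
    study: ExpressionStudy, how: str = "max-variance"
) -> pd.DataFrame:
    """Collapse the probe matrix to one row per gene.

    ``how`` is one of ``max-variance`` (keep the most variable probe of
    each gene, the default), ``mean`` (average the probes) or
    ``max-mean`` (keep the probe with the highest mean).  Probes without
    a gene annotation are dropped.
    """
    gene = study.probe_to_gene
    vals = study.values[gene != ""]
    gene = gene[gene != ""]
    if how == "mean":
        return vals.groupby(gene.values).mean()
    if how == "max-variance":
        score = vals.var(axis=1, ddof=1)
    elif how == "max-mean":
        score = vals.mean(axis=1)
    else:
        raise ValueError(f"unknown collapse rule: {how!r}")
    # deterministic winner: score desc, then probe id
    order = pd.DataFrame({"g": gene.values, "s": -score.values}, index=vals.index)
    order = order.sort_values(["g", "s"], kind="mergesort")
    winners = order.groupby("g", sort=False).head(1).index
    out = vals.loc[winners]
    out.index = gene.loc[winners].values
    return out.sort_index()


def rank_by_metric(
    study: ExpressionStudy,
    class_a: str,
    class_b: str,
    collapse: str = "max-variance",
) -> RankedList:
    """Rank genes by difference of class means (log2 fold change).

    Per gene: score = mean(log2 values in ``class_a``) minus mean in
    ``class_b``; genes are ordered by descending score (ties broken by
    gene symbol).
    """
    a_cols = study.samples_of(class_a)
    b_cols = study.samples_of(class_b)
    by_gene = collapse_probes(study, collapse)
    score = by_gene[a_cols].mean(axis=1) - by_gene[b_cols].mean(axis=1)
    return RankedList.from_series(score)


# ---------------------------------------------------------------------------
# Enrichment score

def enrichment_score(
    ranked: RankedList, geneset: GeneSet, p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and full running profile.

    Raises ``ValueError`` when the set does not intersect the ranked
    universe (an unusable set) or swallows it whole (no misses to walk).
    """
    ids = np.asarray(ranked.ids, dtype=object)
    member = np.isin(ids, tuple(geneset.genes))
    n = len(ids)
    k = int(member.sum())
    if k == 0:
        raise ValueError(
            f"gene set {geneset.name!r} has no members in the ranked list"
        )
    if k == n:
        raise ValueError(
            f"gene set {geneset.name!r} covers the whole ranked universe"
        )
    scores = ranked.score_array()
    w = np.abs(scores) ** p
    hit_w = np.where(member, w, 0.0)
    total = hit_w.sum()
    if total <= 0:  # all member scores zero: fall back to unweighted hits
        hit_w = member.astype(float)
        total = float(k)
    steps = hit_w / total - np.where(member, 0.0, 1.0 / (n - k))
    profile = np.cumsum(steps)
    # exact positive/negative magnitude ties resolve to the positive side
    hi = float(profile.max())
    lo = float(profile.min())
    es = hi if hi >= -lo else lo
    return es, profile


def _es_batch(hit_idx: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """ES for many hit-index sets at once, O(k) per set.

    ``hit_idx`` is a (B, k) matrix of ascending hit positions into a
    ranked list of length ``n``; ``weights`` holds |score|^p per rank.
    Between hits the running sum falls linearly, so its extremes occur
    immediately after a hit (candidate maxima) or just before one
    (candidate minima); scanning those 2k candidates reproduces the full
    walk exactly.
    """
    b, k = hit_idx.shape
    w = weights[hit_idx]
    tot = w.sum(axis=1, keepdims=True)
    uniform = tot <= 0
    w = np.where(uniform, 1.0, w)
    tot = np.where(uniform, float(k), tot)
    cw = np.cumsum(w, axis=1) / tot
    j = np.arange(1, k + 1)
    miss = 1.0 / (n - k)
    after = cw - (hit_idx + 1 - j) * miss
    before = np.concatenate(
        [np.zeros((b, 1)), cw[:, :-1]], axis=1
    ) - (hit_idx - (j - 1)) * miss
    pos = after.max(axis=1)
    neg = before.min(axis=1)
    return np.where(pos >= -neg, pos, neg)


def _null_es(
    n: int,
    k: int,
    weights: np.ndarray,
    n_perm: int,
    seed: int,
    stream: int,
) -> np.ndarray:
    """Gene-set permutation null: ES of random k-subsets of the universe."""
    rng = np.random.default_rng([seed, stream])
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    idx.sort(axis=1)
    return _es_batch(idx, weights, n)


def _leading_edge(
    ranked: RankedList, member: np.ndarray, profile: np.ndarray, es: float
) -> tuple[str, ...]:
    ids = np.asarray(ranked.ids, dtype=object)
    if es >= 0:
        i = int(np.argmax(profile))
        sel = member & (np.arange(len(ids)) <= i)
    else:
        i = int(np.argmin(profile))
        sel = member & (np.arange(len(ids)) >= i)
    return tuple(ids[sel])


def gsea_preranked(
    ranked: RankedList,
    genesets: list[GeneSet],
    config: GseaConfig = GseaConfig(),
) -> list[EnrichmentResult]:
    """Permutation GSEA of gene sets against a supplied ranked list.

    Sets with no usable members, or at least as large as the ranked
    universe, are skipped with a warning.  Results come back in input
    order (skipped sets omitted).
    """
    n = len(ranked)
    weights = np.abs(ranked.score_array()) ** config.weight_exponent
    ids = np.asarray(ranked.ids, dtype=object)

    observed: list[dict] = []
    pooled_null_nes: list[np.ndarray] = []
    for stream, gs in enumerate(genesets):
        member = np.isin(ids, tuple(gs.genes))
        k = int(member.sum())
        if k == 0 or k >= n:
            warnings.warn(
                f"skipping gene set {gs.name!r}: {k} usable members in a "
                f"universe of {n}",
                stacklevel=2,
            )
            continue
        es, profile = enrichment_score(ranked, gs, config.weight_exponent)
        null = _null_es(n, k, weights, config.n_perm, config.seed, stream)

        pos = null[null >= 0]
        neg = null[null < 0]
        if es >= 0:
            same = pos
            nominal_p = float((same >= es).mean()) if same.size else 1.0
        else:
            same = neg
            nominal_p = float((same <= es).mean()) if same.size else 1.0
        mean_pos = float(pos.mean()) if pos.size else np.nan
        mean_neg = float(np.abs(neg).mean()) if neg.size else np.nan
        denom = mean_pos if es >= 0 else mean_neg
        if not np.isfinite(denom) or denom == 0:
            denom = float(np.abs(null).mean()) or 1.0
        nes = es / denom
        null_nes = np.where(
            null >= 0,
            null / (mean_pos if np.isfinite(mean_pos) and mean_pos else denom),
            null / (mean_neg if np.isfinite(mean_neg) and mean_neg else denom),
        )
        pooled_null_nes.append(null_nes)
        observed.append(
            {
                "gs": gs,
                "es": es,
                "nes": nes,
                "p": nominal_p,
                "k": k,
                "le": _leading_edge(ranked, member, profile, es),
                "profile": profile,
            }
        )

    if not observed:
        return []
    null_nes_all = np.concatenate(pooled_null_nes)
    obs_nes = np.array([o["nes"] for o in observed])
    results = []
    for o in observed:
        nes = o["nes"]
        if nes >= 0:
            null_side = null_nes_all[null_nes_all >= 0]
            null_frac = (
                float((null_side >= nes).mean()) if null_side.size else 0.0
            )
            obs_side = obs_nes[obs_nes >= 0]
            obs_frac = float((obs_side >= nes).mean())
        else:
            null_side = null_nes_all[null_nes_all < 0]
            null_frac = (
                float((null_side <= nes).mean()) if null_side.size else 0.0
            )
            obs_side = obs_nes[obs_nes < 0]
            obs_frac = float((obs_side <= nes).mean())
        fdr = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
        results.append(
            EnrichmentResult(
                geneset_name=o["gs"].name,
                es=o["es"],
                nes=float(nes),
                nominal_p=o["p"],
                fdr=fdr,
                size=o["k"],
                leading_edge=o["le"],
                running_profile=o["profile"],
            )
        )
    return results


def gsea_run(
    study: ExpressionStudy,
    class_a: str,
    class_b: str,
    genesets: list[GeneSet],
    config: GseaConfig = GseaConfig(),
    collapse: str = "max-variance",
) -> list[EnrichmentResult]:
    """Two-class GSEA: rank genes by difference of class means, then score."""
    ranked = rank_by_metric(study, class_a, class_b, collapse)
    return gsea_preranked(ranked, genesets, config)


def nondifferential_geneset(
    study: ExpressionStudy,
    class_a: str,
    class_b: str,
    max_abs_diff: float = 0.1,
    name: str = "non_differential_control",
    collapse: str = "max-variance",
) -> GeneSet:
    """Negative-control set: genes with |difference of class means| below a cutoff."""
    ranked = rank_by_metric(study, class_a, class_b, collapse)
    score = ranked.to_series()
    genes = tuple(score.index[score.abs() <= max_abs_diff])
    return GeneSet(name, f"|diff of class means| <= {max_abs_diff}", genes)
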