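"""Cross-omics integration of expression signatures with promoter methylation.

An expression-derived GeneSet is converted to a set of methylation probe
identifiers (promoter probes of its genes, by default), every retained
probe is ranked by the signed Δβ of group medians between two donor-paired
subsets (test - reference, descending), and the probe set is scored against
that ranking by pre-ranked permutation GSEA.  With this orientation a
negative enrichment (NES < 0) means the signature's promoters are
hypomethylated in the test subset.

For a stable FDR the real probe set is evaluated alongside size-matched
decoy probe sets sampled from the ranked probe universe, mirroring the
common practice of padding a small gene-set collection with a large public
catalog before permutation testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gsea import EnrichmentResult, GseaConfig, gsea_preranked
from .io_formats import GeneSet, RankedList
from .methylome import (
    PROMOTER_REGIONS,
    MethylationStudy,
    dm_test,
    promoter_probes,
)

__all__ = ["ProbeSet", "genes_to_probes", "rank_delta_beta", "integrate"]


@dataclass(frozen=True)
class ProbeSet:
    """Methylation-probe translation of an expression GeneSet."""

    name: str
    probes: tuple[str, ...]
    source_genes_mapped: int
    source_genes_unmapped: tuple[str, ...]

    def as_geneset(self) -> GeneSet:
        return GeneSet(self.name, "probe translation", self.probes)

    def __len__(self) -> int:
        return len(self.probes)


def genes_to_probes(
    geneset: GeneSet,
    study: MethylationStudy,
    promoter_only: bool = True,
) -> ProbeSet:
    """Translate gene symbols into methylation probe identifiers.

    Takes the union of each gene's (promoter) probes.  Genes without any
    matching probe are reported in ``source_genes_unmapped`` rather than
    silently dropped; if no gene maps at all the set is unusable and a
    ``ValueError`` is raised.
    """
    ann = study.annotation
    if promoter_only:
        ann = ann[ann["region"].isin(PROMOTER_REGIONS)]
    by_gene = ann.groupby("gene").groups
    probes: list[str] = []
    unmapped: list[str] = []
    for gene in geneset.genes:
        hit = by_gene.get(gene)
        if hit is None or len(hit) == 0:
            unmapped.append(gene)
        else:
            probes.extend(hit)
    if not probes:
        raise ValueError(
            f"gene set {geneset.name!r}: no gene maps to a "
            f"{'promoter ' if promoter_only else ''}methylation probe"
        )
    return ProbeSet(
        name=geneset.name,
        probes=tuple(dict.fromkeys(probes)),
        source_genes_mapped=len(geneset.genes) - len(unmapped),
        source_genes_unmapped=tuple(unmapped),
    )


def rank_delta_beta(
    study: MethylationStudy,
    test_subset: str,
    reference_subset: str,
    promoter_only: bool = False,
) -> RankedList:
    """Probes ranked by signed Δβ of medians (test - reference), descending."""
    if promoter_only:
        keep = study.annotation["region"].isin(PROMOTER_REGIONS)
        study = study.subset_probes(study.beta.index[keep])
    dm = dm_test(study, test_subset, reference_subset)
    return RankedList.from_series(dm["delta_beta"])


def _decoy_probesets(
    universe: tuple[str, ...], size: int, count: int, seed: int
) -> list[GeneSet]:
    rng = np.random.default_rng([seed, 0x0DEC0])
    ids = np.asarray(universe, dtype=object)
    decoys = []
    for i in range(count):
        pick = rng.choice(len(ids), size=size, replace=False)
        decoys.append(
            GeneSet(f"decoy_{i:03d}", "size-matched decoy", tuple(ids[pick]))
        )
    return decoys


def integrate(
    expr_geneset: GeneSet,
    meth_study: MethylationStudy,
    test_subset: str,
    reference_subset: str,
    config: GseaConfig = GseaConfig(),
    promoter_only: bool = True,
    n_decoys: int = 100,
    rank_promoter_only: bool = False,
) -> tuple[EnrichmentResult, ProbeSet]:
    """Enrichment of an expression signature in the methylation ranking.

    Returns the EnrichmentResult of the translated probe set against the
    Δβ ranking (decoy results are used for FDR pooling but not
    returned).  ``nes < 0`` with a low FDR means the signature genes'
    promoters are coherently hypomethylated in ``test_subset``.
    """
    probeset = genes_to_probes(expr_geneset, meth_study, promoter_only)
    ranked = rank_delta_beta(
        meth_study, test_subset, reference_subset, rank_promoter_only
    )
    universe = set(ranked.ids)
    usable = tuple(p for p in probeset.probes if p in universe)
    if not usable:
        raise ValueError(
            f"no probe of set {probeset.name!r} is present in the ranking"
        )
    sets = [GeneSet(probeset.name, "probe translation", usable)]
    if n_decoys > 0:
        sets += _decoy_probesets(
            tuple(ranked.ids), len(usable), n_decoys, config.seed
        )
    results = gsea_preranked(ranked, sets, config)
    real = next(r for r in results if r.geneset_name == probeset.name)
    return real, probeset
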