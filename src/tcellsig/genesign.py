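"""Min/max derivation of subset-specific gene signatures.

A probe is called specific for a test subset when its minimal expression
over the test replicates exceeds its maximal expression over the reference
replicates — a conservative, threshold-free rule that only fires when the
two groups of replicates do not overlap at all.  To limit the signatures to
regulated probes, a fold-change pre-filter removes probes whose max/min
ratio across all samples of the study (on the linear scale) falls below a
cutoff, 1.2 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionStudy
from .io_formats import GeneSet

__all__ = ["SignatureSpec", "regulation_filter", "derive_geneset"]


@dataclass(frozen=True)
class SignatureSpec:
    """Configuration of one min/max signature derivation.

    ``regulation_ratio`` is the linear-scale max/min cutoff of the
    pre-filter.  ``ratio_scale`` selects how the cutoff is interpreted
    against log2 data: ``"linear"`` (default) treats it as a fold change,
    i.e. keeps probes with log2 range >= log2(ratio); ``"log2-input"``
    applies the ratio directly to the log2 values.
    """

    test_subset: str
    reference_subset: str
    regulation_ratio: float = 1.2
    ratio_scale: str = "linear"

    def __post_init__(self) -> None:
        if self.regulation_ratio <= 1:
            raise ValueError("regulation_ratio must be > 1")
        if self.ratio_scale not in ("linear", "log2-input"):
            raise ValueError(f"unknown ratio_scale: {self.ratio_scale!r}")


def regulation_filter(
    study: ExpressionStudy,
    ratio: float = 1.2,
    ratio_scale: str = "linear",
) -> pd.Index:
    """Probes regulated somewhere in the study.

    On the default linear scale a probe passes when its linear max/min
    fold change over *all* samples is at least ``ratio``, i.e. its log2
    range is at least log2(ratio).
    """
    if ratio <= 1:
        raise ValueError("regulation ratio must be > 1")
    vals = study.values
    if ratio_scale == "linear":
        keep = (vals.max(axis=1) - vals.min(axis=1)) >= np.log2(ratio)
    elif ratio_scale == "log2-input":
        lo = vals.min(axis=1)
        hi = vals.max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            keep = (hi / lo) >= ratio
        keep &= lo > 0
    else:
        raise ValueError(f"unknown ratio_scale: {ratio_scale!r}")
    return vals.index[keep]


def derive_geneset(study: ExpressionStudy, spec: SignatureSpec) -> GeneSet:
    """Derive the subset-specific GeneSet for ``spec.test_subset``.

    Applies the regulation pre-filter, keeps probes whose minimum over
    the test replicates strictly exceeds their maximum over the reference
    replicates, and flattens the surviving probes to unique gene symbols
    (a gene enters the set if any of its probes is specific).  An empty
    derivation yields an empty GeneSet, not an error.
    """
    test_cols = study.samples_of(spec.test_subset)
    ref_cols = study.samples_of(spec.reference_subset)
    kept = regulation_filter(
        study, spec.regulation_ratio, spec.ratio_scale
    )
    vals = study.values.loc[kept]
    specific = vals[test_cols].min(axis=1) > vals[ref_cols].max(axis=1)
    probes = vals.index[specific]
    genes = [
        g for g in study.probe_to_gene.loc[probes].tolist() if g
    ]
    name = f"{spec.test_subset}_vs_{spec.reference_subset}"
    return GeneSet(
        name=name,
        description=(
            f"min/max specific genes, ratio>={spec.regulation_ratio}"
        ),
        genes=tuple(genes),
    )
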