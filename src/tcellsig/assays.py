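"""Calculators for the bench-assay readouts accompanying the array pipeline.

* relative qPCR expression by the ΔΔCp method against a housekeeping gene
  (EEF1A1 by default) and a calibrator subset,
* ChIP-qPCR enrichment as percent of input chromatin, normalized to a
  pan-H3 immunoprecipitation,
* cytotoxicity as percent specific lysis (caspase-3⁺ targets above the
  no-effector control),
* single-cell qPCR co-expression: per-subset fractions of anchor-positive
  cells and of double-positive cells among anchor-positive ones,
* bisulphite pyrosequencing summaries over the 34 CpG sites of the PRF1
  promoter, split into distal / intermediate / proximal regions.

Cp tables are tidy DataFrames with one row per well:
``sample_id, donor, subset, gene (or region/antibody), cp, replicate``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ddcp_fold_change",
    "ddcp_summary",
    "chip_percent_input",
    "percent_lysis",
    "coexpression_proportions",
    "qc_cells",
    "pyroseq_summary",
    "PYROSEQ_REGIONS",
    "pairwise_mannwhitney",
]

#: default CpG-site regions of the PRF1 promoter (1-based site numbers)
PYROSEQ_REGIONS: dict[str, tuple[int, int]] = {
    "distal": (1, 15),
    "intermediate": (16, 28),
    "proximal": (29, 34),
}


def _mean_cp(table: pd.DataFrame, by: list[str]) -> pd.Series:
    """Average Cp over technical replicates."""
    return table.groupby(by, sort=False)["cp"].mean()


# ---------------------------------------------------------------------------
# qPCR ΔΔCp

def ddcp_fold_change(
    table: pd.DataFrame,
    target_gene: str,
    calibrator_subset: str,
    reference_gene: str = "EEF1A1",
) -> pd.DataFrame:
    """Relative expression by the ΔΔCp method.

    Per (donor, subset): ΔCp = Cp(target) - Cp(reference gene); then
    ΔΔCp = ΔCp - ΔCp of the same donor's calibrator subset; log2 fold
    change = -ΔΔCp and fold change = 2^(-ΔΔCp).  Technical replicates
    are averaged first.  Missing reference or calibrator measurements
    raise with the offending sample named.
    """
    cp = _mean_cp(table, ["donor", "subset", "gene"]).unstack("gene")
    for gene in (target_gene, reference_gene):
        if gene not in cp.columns:
            raise ValueError(f"gene {gene!r} absent from Cp table")
    missing = cp[reference_gene].isna() | cp[target_gene].isna()
    if missing.any():
        raise ValueError(
            f"missing Cp for {cp.index[missing].tolist()[:5]}"
        )
    dcp = cp[target_gene] - cp[reference_gene]
    calib = dcp.xs(calibrator_subset, level="subset")
    ddcp = dcp - calib.reindex(dcp.index.get_level_values("donor")).values
    if ddcp.isna().any():
        bad = ddcp.index[ddcp.isna()].tolist()[:5]
        raise ValueError(f"no calibrator ΔCp for donors of {bad}")
    out = ddcp.reset_index()
    out.columns = ["donor", "subset", "ddcp"]
    out["log2_fold_change"] = -out["ddcp"]
    out["fold_change"] = 2.0 ** out["log2_fold_change"]
    return out


def ddcp_summary(fold_changes: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of log2 fold change per subset."""
    g = fold_changes.groupby("subset", sort=False)["log2_fold_change"]
    return pd.DataFrame(
        {
            "median": g.median(),
            "iqr_low": g.quantile(0.25),
            "iqr_high": g.quantile(0.75),
            "n_donors": g.count(),
        }
    )


# ---------------------------------------------------------------------------
# ChIP-qPCR percent input

def chip_percent_input(
    table: pd.DataFrame,
    ip_antibody: str,
    input_fraction: float = 0.01,
    h3_antibody: str = "H3",
    input_label: str = "input",
    mode: str = "ratio",
) -> pd.DataFrame:
    """ChIP enrichment as % of input, normalized to the pan-H3 IP.

    The input Cp is first adjusted for the fraction of chromatin set
    aside (``adjusted = Cp_input - log2(1/input_fraction)``), then
    ``%input = 100 * 2^(adjusted - Cp_IP)`` for each antibody and
    region.  Normalization modes: ``"ratio"`` (default) reports
    %input(target) / %input(H3); ``"subtract"`` subtracts the H3 ΔCp
    instead, i.e. reports 100 * 2^(Cp_H3 - Cp_IP) — the two agree up to
    the H3 recovery scale.

    The table needs columns ``donor, region, antibody, cp``.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    cp = _mean_cp(table, ["donor", "region", "antibody"]).unstack("antibody")
    for ab in (input_label, ip_antibody, h3_antibody):
        if ab not in cp.columns or cp[ab].isna().any():
            raise ValueError(f"missing Cp rows for antibody {ab!r}")
    adjusted_input = cp[input_label] - np.log2(1.0 / input_fraction)
    pct_target = 100.0 * 2.0 ** (adjusted_input - cp[ip_antibody])
    pct_h3 = 100.0 * 2.0 ** (adjusted_input - cp[h3_antibody])
    if mode == "ratio":
        normalized = pct_target / pct_h3
    elif mode == "subtract":
        normalized = 100.0 * 2.0 ** (cp[h3_antibody] - cp[ip_antibody])
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    out = pd.DataFrame(
        {
            "percent_input": pct_target,
            "percent_input_h3": pct_h3,
            "normalized": normalized,
        }
    )
    return out.reset_index()


# ---------------------------------------------------------------------------
# Cytotoxicity

def percent_lysis(
    caspase3_pos_with_effectors: float | np.ndarray,
    caspase3_pos_control: float | np.ndarray,
) -> float | np.ndarray:
    """Percent specific lysis: effector-well caspase-3⁺ minus control.

    Negative differences (control above effector wells) are floored at
    zero with a warning — spontaneous-death fluctuations cannot lyse a
    negative number of cells.
    """
    eff = np.asarray(caspase3_pos_with_effectors, dtype=float)
    ctl = np.asarray(caspase3_pos_control, dtype=float)
    for name, x in (("effector", eff), ("control", ctl)):
        if (x < 0).any() or (x > 100).any():
            raise ValueError(f"{name} percentages must lie in [0, 100]")
    diff = eff - ctl
    if (diff < 0).any():
        warnings.warn(
            "control wells exceed effector wells; lysis floored at 0",
            stacklevel=2,
        )
    out = np.clip(diff, 0.0, None)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Single-cell co-expression

def qc_cells(
    table: pd.DataFrame,
    housekeeping_gene: str,
    min_level: float = 0.0,
    iqr_fence: float = 1.5,
) -> pd.DataFrame:
    """Keep wells that look like intact single cells.

    A well passes when its housekeeping-gene level exceeds
    ``min_level`` and lies inside the Tukey fence (median ± iqr_fence x
    IQR) of its subset.
    """
    hk = table[housekeeping_gene]
    ok = hk > min_level
    for subset, grp in table.groupby("subset"):
        q1, q3 = grp[housekeeping_gene].quantile([0.25, 0.75])
        fence_lo = q1 - iqr_fence * (q3 - q1)
        fence_hi = q3 + iqr_fence * (q3 - q1)
        inside = hk.between(fence_lo, fence_hi)
        ok &= inside | (table["subset"] != subset)
    return table[ok]


def coexpression_proportions(
    table: pd.DataFrame,
    anchor_gene: str = "PRF1",
    partner_genes: list[str] | None = None,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-subset anchor-positive and co-expression fractions.

    A gene is positive in a cell when its level exceeds ``threshold``
    (limit of detection).  Per subset the anchor fraction is
    anchor⁺/total cells; each partner's co-expression is
    (anchor⁺ AND partner⁺)/anchor⁺, reported as NaN (undefined, not 0)
    when the subset has no anchor-positive cell.
    """
    if partner_genes is None:
        partner_genes = [
            c for c in table.columns if c not in ("subset", anchor_gene)
        ]
    rows = []
    for subset, grp in table.groupby("subset", sort=False):
        anchor_pos = grp[anchor_gene] > threshold
        row = {
            "subset": subset,
            "n_cells": len(grp),
            f"{anchor_gene}_fraction": anchor_pos.mean(),
        }
        for gene in partner_genes:
            if anchor_pos.sum() == 0:
                row[gene] = np.nan
            else:
                both = anchor_pos & (grp[gene] > threshold)
                row[gene] = both.sum() / anchor_pos.sum()
        rows.append(row)
    return pd.DataFrame(rows).set_index("subset")


# ---------------------------------------------------------------------------
# Pyrosequencing

def pyroseq_summary(
    table: pd.DataFrame,
    regions: dict[str, tuple[int, int]] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-CpG and per-region methylation summaries.

    ``table`` is donors x CpG sites (columns in site order, percent
    methylation in [0, 100]).  Returns a per-CpG frame (median, IQR
    bounds) and a per-region Series of medians of the per-CpG medians.
    The column count must cover every site of the region map (34 for
    the default PRF1 promoter map).
    """
    regions = PYROSEQ_REGIONS if regions is None else regions
    n_sites = max(hi for _, hi in regions.values())
    if table.shape[1] != n_sites:
        raise ValueError(
            f"expected {n_sites} CpG columns, got {table.shape[1]}"
        )
    vals = table.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 100).any():
        raise ValueError("methylation percentages must lie in [0, 100]")
    per_cpg = pd.DataFrame(
        {
            "median": np.median(vals, axis=0),
            "iqr_low": np.quantile(vals, 0.25, axis=0),
            "iqr_high": np.quantile(vals, 0.75, axis=0),
        },
        index=pd.RangeIndex(1, n_sites + 1, name="cpg_site"),
    )
    per_region = pd.Series(
        {
            name: float(per_cpg["median"].loc[lo:hi].median())
            for name, (lo, hi) in regions.items()
        },
        name="median_methylation",
    )
    return per_cpg, per_region


# ---------------------------------------------------------------------------
# Thin comparison helpers

def pairwise_mannwhitney(
    values: pd.Series, groups: pd.Series, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Mann-Whitney U for selected two-by-two group comparisons."""
    rows = []
    for a, b in pairs:
        u, p = stats.mannwhitneyu(
            values[groups == a], values[groups == b], alternative="two-sided"
        )
        rows.append({"group_a": a, "group_b": b, "U": u, "p_value": p})
    return pd.DataFrame(rows)
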