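"""Infinium 450K-style methylation pipeline.

Covers the array-level arithmetic (β = M/(U+M), M-value = logit2 β), probe
quality filtering (detection p-value, cross-reactive probe removal,
SNP-overlap probes retained), peak-based correction of the type-I/type-II
design bias, and paired differential methylation between donor-matched cell
subsets: a paired t-test on M-values combined with a Δβ of group medians,
calling a CpG differentially methylated when p < 1e-4 and |Δβ| > 0.1.

Probe annotation is a DataFrame indexed by probe id with columns ``gene``,
``region`` (TSS1500/TSS200/5'UTR/1stExon/Body/3'UTR/intergenic),
``design_type`` ("I"/"II") and boolean ``cross_reactive``/``snp_overlap``
flags.  Promoter probes are those in TSS1500, TSS200, 5'UTR or 1stExon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import validate_design

__all__ = [
    "MethylationStudy",
    "PROMOTER_REGIONS",
    "REGION_CLASSES",
    "compute_beta",
    "filter_probes",
    "peak_correct",
    "m_values",
    "beta_from_m",
    "dm_test",
    "promoter_probes",
    "region_proportions",
]

PROMOTER_REGIONS = ("TSS1500", "TSS200", "5'UTR", "1stExon")
REGION_CLASSES = PROMOTER_REGIONS + ("Body", "3'UTR", "intergenic")

ANNOTATION_COLUMNS = (
    "gene",
    "region",
    "design_type",
    "cross_reactive",
    "snp_overlap",
)

#: β is clipped into this open interval before the logit so M stays finite
BETA_CLIP = 1e-6


@dataclass
class MethylationStudy:
    """β-values with probe annotation and sample design.

    ``beta`` is probes x samples in [0, 1].  ``raw_m``/``raw_u`` (signal
    intensities) and ``detection_p`` are optional and share the beta
    matrix layout where present.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame
    design: pd.DataFrame
    raw_m: pd.DataFrame | None = None
    raw_u: pd.DataFrame | None = None
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.design = validate_design(self.design)
        cols = list(self.beta.columns)
        if sorted(cols) != sorted(self.design["sample_id"]):
            raise ValueError("design sample_ids do not match beta columns")
        self.design = (
            self.design.set_index("sample_id").loc[cols].reset_index()
        )
        missing = [
            c for c in ANNOTATION_COLUMNS if c not in self.annotation.columns
        ]
        if missing:
            raise ValueError(f"annotation is missing columns: {missing}")
        if not self.annotation.index.equals(self.beta.index):
            if set(self.annotation.index) >= set(self.beta.index):
                self.annotation = self.annotation.loc[self.beta.index]
            else:
                lost = set(self.beta.index) - set(self.annotation.index)
                raise ValueError(
                    f"annotation does not cover all probes, e.g. "
                    f"{sorted(lost)[:5]}"
                )
        bad_type = set(self.annotation["design_type"]) - {"I", "II"}
        if bad_type:
            raise ValueError(f"unknown Infinium design types: {bad_type}")
        vals = self.beta.to_numpy()
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    def samples_of(self, subset: str) -> list[str]:
        sel = self.design.loc[self.design["subset"] == subset, "sample_id"]
        if sel.empty:
            raise KeyError(f"unknown subset label: {subset!r}")
        return sel.tolist()

    def subset_probes(self, probes: pd.Index) -> "MethylationStudy":
        return replace(
            self,
            beta=self.beta.loc[probes],
            annotation=self.annotation.loc[probes],
            design=self.design.copy(),
            raw_m=None if self.raw_m is None else self.raw_m.loc[probes],
            raw_u=None if self.raw_u is None else self.raw_u.loc[probes],
            detection_p=(
                None
                if self.detection_p is None
                else self.detection_p.loc[probes]
            ),
        )


def compute_beta(raw_m: pd.DataFrame, raw_u: pd.DataFrame) -> pd.DataFrame:
    """β = M / (U + M) elementwise; zero total signal maps to NaN."""
    m = raw_m.to_numpy(dtype=float)
    u = raw_u.to_numpy(dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("raw signals must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / total, np.nan)
    return pd.DataFrame(beta, index=raw_m.index, columns=raw_m.columns)


def m_values(beta: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """M-value = log2(β / (1 - β)), after clipping β away from 0 and 1."""
    arr = np.asarray(beta, dtype=float)
    clipped = np.clip(arr, BETA_CLIP, 1 - BETA_CLIP)
    m = np.log2(clipped / (1 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def beta_from_m(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`m_values` (logistic in base 2)."""
    arr = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + 2.0 ** (-arr))


def filter_probes(
    study: MethylationStudy,
    detection_threshold: float = 0.05,
    detection_rule: str = "any",
    detection_fraction: float = 0.0,
) -> tuple[MethylationStudy, dict[str, int]]:
    """Quality-filter probes; returns the filtered study and removal counts.

    A probe fails detection when its detection p-value is >= the
    threshold in: any sample (``detection_rule="any"``, the default,
    strict), all samples (``"all"``), or more than ``detection_fraction``
    of samples (``"fraction"``).  Cross-reactive probes are dropped;
    probes overlapping SNPs are deliberately retained (within-donor
    comparisons are immune to genotype confounding).
    """
    if study.detection_p is None:
        raise ValueError("filter_probes requires detection p-values")
    fail = study.detection_p.to_numpy() >= detection_threshold
    if detection_rule == "any":
        det_fail = fail.any(axis=1)
    elif detection_rule == "all":
        det_fail = fail.all(axis=1)
    elif detection_rule == "fraction":
        det_fail = fail.mean(axis=1) > detection_fraction
    else:
        raise ValueError(f"unknown detection_rule: {detection_rule!r}")
    cross = study.annotation["cross_reactive"].to_numpy(bool)
    keep = ~det_fail & ~cross
    report = {
        "removed_detection": int(det_fail.sum()),
        "removed_cross_reactive": int((cross & ~det_fail).sum()),
        "retained_snp_overlap": int(
            (study.annotation["snp_overlap"].to_numpy(bool) & keep).sum()
        ),
        "retained": int(keep.sum()),
    }
    return study.subset_probes(study.beta.index[keep]), report


def _two_peaks(m: np.ndarray, grid: np.ndarray) -> tuple[float, float] | None:
    """(unmethylated, methylated) KDE peak positions in M-space, or None.

    Uses a Gaussian KDE with Silverman bandwidth; local maxima below 5%
    of the tallest peak are treated as noise.  Returns the highest peak
    on each side of M = 0, or None when either side lacks one (unimodal
    distribution).
    """
    density = stats.gaussian_kde(m)(grid)
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    modes = grid[1:-1][interior]
    heights = density[1:-1][interior]
    keep = heights >= 0.05 * heights.max()
    modes, heights = modes[keep], heights[keep]
    lo = modes < 0
    hi = modes > 0
    if not lo.any() or not hi.any():
        return None
    u = modes[lo][np.argmax(heights[lo])]
    v = modes[hi][np.argmax(heights[hi])]
    return float(u), float(v)


def peak_correct(study: MethylationStudy) -> MethylationStudy:
    """Align type-II β peaks onto the type-I peaks, per sample.

    For each sample the unmethylated and methylated density peaks of the
    type-I and type-II M-value distributions are located by kernel
    density estimation; type-II M-values are then linearly rescaled so
    that their two peaks coincide with the type-I peaks, and converted
    back to β.  Type-I values pass through unchanged.  A sample whose
    type-I or type-II distribution is not bimodal is left uncorrected
    with a warning.  The transform is affine with positive slope in
    M-space, hence monotone, and the logistic return keeps β in (0, 1).
    """
    types = study.annotation["design_type"].to_numpy()
    is_ii = types == "II"
    if not is_ii.any():
        return replace(study, beta=study.beta.copy())
    grid = np.linspace(-10, 10, 801)
    beta = study.beta.to_numpy(dtype=float).copy()
    m = np.asarray(m_values(beta))
    for j, sample in enumerate(study.beta.columns):
        peaks_i = _two_peaks(m[~is_ii, j], grid)
        peaks_ii = _two_peaks(m[is_ii, j], grid)
        if peaks_i is None or peaks_ii is None:
            warnings.warn(
                f"sample {sample!r}: type-I or type-II M-value distribution "
                "is not bimodal; left uncorrected",
                stacklevel=2,
            )
            continue
        (u1, m1), (u2, m2) = peaks_i, peaks_ii
        if m2 - u2 <= 0:
            warnings.warn(
                f"sample {sample!r}: degenerate type-II peaks; left "
                "uncorrected",
                stacklevel=2,
            )
            continue
        slope = (m1 - u1) / (m2 - u2)
        rescaled = (m[is_ii, j] - u2) * slope + u1
        beta[is_ii, j] = beta_from_m(rescaled)
    out = pd.DataFrame(
        beta, index=study.beta.index, columns=study.beta.columns
    )
    return replace(study, beta=out)


def _paired_columns(
    study: MethylationStudy, test_subset: str, reference_subset: str
) -> tuple[list[str], list[str]]:
    d = study.design
    test = d[d["subset"] == test_subset].set_index("donor")["sample_id"]
    ref = d[d["subset"] == reference_subset].set_index("donor")["sample_id"]
    if test.empty:
        raise KeyError(f"unknown subset label: {test_subset!r}")
    if ref.empty:
        raise KeyError(f"unknown subset label: {reference_subset!r}")
    donors = sorted(set(test.index) & set(ref.index))
    missing = sorted(set(test.index) ^ set(ref.index))
    if missing:
        raise ValueError(
            f"subsets {test_subset!r}/{reference_subset!r} are not fully "
            f"donor-paired; unpaired donors: {missing}"
        )
    if len(donors) < 3:
        raise ValueError("paired test needs >= 3 donor pairs")
    return test.loc[donors].tolist(), ref.loc[donors].tolist()


def dm_test(
    study: MethylationStudy,
    test_subset: str,
    reference_subset: str,
    p_threshold: float = 1e-4,
    delta_threshold: float = 0.1,
) -> pd.DataFrame:
    """Paired differential methylation between two donor-matched subsets.

    Per probe: a two-sided paired t-test on M-values across donor pairs,
    and Δβ = median β(test) - median β(reference) (stored signed; the
    call uses its absolute value).  Returns a DataFrame indexed by probe
    with columns ``delta_beta``, ``m_t_statistic``, ``p_value`` and
    ``called`` where called = (p < p_threshold) and (|Δβ| >
    delta_threshold).
    """
    test_cols, ref_cols = _paired_columns(study, test_subset, reference_subset)
    beta_t = study.beta[test_cols].to_numpy(dtype=float)
    beta_r = study.beta[ref_cols].to_numpy(dtype=float)
    m_t = np.asarray(m_values(beta_t))
    m_r = np.asarray(m_values(beta_r))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_val = stats.ttest_rel(m_t, m_r, axis=1)
    # probes with zero variance of paired differences: t undefined, p -> 1
    t_stat = np.nan_to_num(t_stat, nan=0.0)
    p_val = np.where(np.isnan(p_val), 1.0, p_val)
    delta = np.median(beta_t, axis=1) - np.median(beta_r, axis=1)
    called = (p_val < p_threshold) & (np.abs(delta) > delta_threshold)
    return pd.DataFrame(
        {
            "delta_beta": delta,
            "m_t_statistic": t_stat,
            "p_value": p_val,
            "called": called,
        },
        index=study.beta.index,
    )


def promoter_probes(study: MethylationStudy, gene: str) -> list[str]:
    """Probes annotated to ``gene`` in a promoter region class.

    Promoter = TSS1500, TSS200, 5'UTR or 1stExon.  An unknown gene gives
    an empty list.
    """
    ann = study.annotation
    sel = (ann["gene"] == gene) & ann["region"].isin(PROMOTER_REGIONS)
    return ann.index[sel].tolist()


def region_proportions(study: MethylationStudy, gene: str) -> pd.Series:
    """Fraction of a gene's promoter probes per region class."""
    probes = promoter_probes(study, gene)
    if not probes:
        return pd.Series(dtype=float)
    counts = study.annotation.loc[probes, "region"].value_counts()
    return counts / counts.sum()
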