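"""Seeded generator of paired expression/methylation studies and assay fixtures.

The generator emulates the study design the pipeline was built for: five
donors, each sorted into six T-cell subsets (naive CD4, central-memory Th1,
CD28⁺ effector-memory Th1, cytotoxic CD4, naive CD8, cytotoxic CD8), with
one expression array and one 450K-style methylation array per sample and
donor-paired structure across subsets.

Planted structure couples the two layers the way the biology does: each
cytotoxic subset carries a set of signature genes whose expression is
shifted up by ``expr_effect`` log2 units in that subset only, and whose
promoter CpG probes are simultaneously hypomethylated by ``meth_effect``
(Δβ, negative) in the same samples.  Methylation baselines are drawn from a
bimodal mixture (modes near β = 0.1 and 0.85, as on real arrays) and
per-sample values from beta distributions around them; type-II probes are
linearly compressed toward β = 0.5 before output so the peak-based design
bias correction has real work to do.

Everything is a pure function of the spec (including its seed): the same
spec yields bitwise-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionStudy
from .methylome import PROMOTER_REGIONS, MethylationStudy

__all__ = [
    "DEFAULT_SUBSETS",
    "StudySpec",
    "GroundTruth",
    "make_study",
    "make_qpcr_fixture",
    "make_chip_fixture",
    "make_singlecell_fixture",
    "make_pyroseq_fixture",
]

DEFAULT_SUBSETS = (
    "CD4_naive",
    "CM_Th1",
    "EM28_Th1",
    "CD4_CTX",
    "CD8_naive",
    "CD8_CTX",
)

_REGION_CHOICES = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1stExon",
    "Body",
    "3'UTR",
    "intergenic",
)
# TSS1500 dominates real promoter annotation; Body is the main non-promoter
_REGION_WEIGHTS = (0.30, 0.17, 0.13, 0.08, 0.22, 0.06, 0.04)


@dataclass(frozen=True)
class StudySpec:
    """Parameters of one synthetic paired study.

    ``expr_effect`` is the planted log2 up-shift of signature genes in
    their subset; ``meth_effect`` the planted Δβ (negative =
    hypomethylation) of those genes' promoter probes.
    ``beta_concentration`` controls per-probe β noise (beta-distribution
    pseudo-count; larger = tighter).  ``donor_effect_sd`` is the standard
    deviation of a per-probe, per-donor random offset on the M (logit2 β)
    scale, shared by all of a donor's samples — the inter-individual
    methylation variability that motivates donor-paired testing.
    ``typeII_compression`` in [0, 1) linearly shrinks type-II β values
    toward 0.5 to mimic the Infinium design bias.
    """

    n_donors: int = 5
    subsets: tuple[str, ...] = DEFAULT_SUBSETS
    n_probes_expr: int = 2000
    n_probes_meth: int = 4000
    n_signature_genes: int = 40
    signature_subsets: tuple[str, ...] = ("CD4_CTX", "CD8_CTX")
    expr_effect: float = 2.0
    meth_effect: float = -0.3
    expr_noise_sd: float = 0.25
    expr_baseline_sd: float = 1.5
    beta_concentration: float = 60.0
    donor_effect_sd: float = 0.5
    typeII_compression: float = 0.15
    detection_fail_rate: float = 0.002
    cross_reactive_rate: float = 0.01
    snp_overlap_rate: float = 0.02
    multiprobe_gene_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_donors", "n_probes_expr", "n_probes_meth",
                     "n_signature_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.subsets:
            raise ValueError("at least one subset is required")
        if not set(self.signature_subsets) <= set(self.subsets):
            raise ValueError("signature_subsets must be among subsets")
        if not 0 <= self.typeII_compression < 1:
            raise ValueError("typeII_compression must be in [0, 1)")
        if abs(self.meth_effect) >= 1:
            raise ValueError("meth_effect must keep beta inside (0, 1)")
        if self.beta_concentration <= 0 or self.expr_noise_sd < 0:
            raise ValueError("noise parameters must be positive")
        if self.n_genes > self.n_probes_meth:
            raise ValueError(
                "n_probes_meth must cover every gene with >= 1 probe"
            )

    @property
    def n_genes(self) -> int:
        extra = int(round(self.n_probes_expr * self.multiprobe_gene_fraction))
        return max(1, self.n_probes_expr - extra)


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery checks."""

    signature_genes: dict[str, tuple[str, ...]]
    hypomethylated_probes: dict[str, tuple[str, ...]]
    assay_effects: dict[str, object] = field(default_factory=dict)


def _design(spec: StudySpec) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{subset}_D{d + 1}",
            "subset": subset,
            "donor": f"D{d + 1}",
        }
        for subset in spec.subsets
        for d in range(spec.n_donors)
    ]
    return pd.DataFrame(rows)


def make_study(
    spec: StudySpec,
) -> tuple[ExpressionStudy, MethylationStudy, GroundTruth]:
    """Generate one paired expression + methylation study.

    See the module docstring for the generative model.  Returns the two
    studies plus the ground truth of planted signature genes and
    hypomethylated promoter probes per signature subset.
    """
    rng = np.random.default_rng(spec.seed)
    design = _design(spec)
    sample_ids = design["sample_id"].tolist()
    n_samples = len(sample_ids)

    # --- expression ---------------------------------------------------
    genes = np.array([f"GENE{i + 1:05d}" for i in range(spec.n_genes)])
    probe_gene_idx = np.concatenate(
        [
            np.arange(spec.n_genes),
            rng.integers(0, spec.n_genes, spec.n_probes_expr - spec.n_genes),
        ]
    )
    expr_probes = np.array(
        [f"ILMN_{i + 1:06d}" for i in range(spec.n_probes_expr)]
    )
    probe_to_gene = pd.Series(genes[probe_gene_idx], index=expr_probes)

    baseline = rng.normal(8.0, spec.expr_baseline_sd, spec.n_probes_expr)
    expr = baseline[:, None] + rng.normal(
        0.0, spec.expr_noise_sd, (spec.n_probes_expr, n_samples)
    )

    # plant disjoint signature gene sets, one per signature subset
    n_sig_total = spec.n_signature_genes * len(spec.signature_subsets)
    if n_sig_total > spec.n_genes:
        raise ValueError("not enough genes for the requested signatures")
    sig_gene_idx = rng.choice(spec.n_genes, n_sig_total, replace=False)
    signature_genes: dict[str, tuple[str, ...]] = {}
    subset_of = design.set_index("sample_id")["subset"]
    for si, subset in enumerate(spec.signature_subsets):
        idx = sig_gene_idx[
            si * spec.n_signature_genes : (si + 1) * spec.n_signature_genes
        ]
        signature_genes[subset] = tuple(sorted(genes[idx]))
        probe_rows = np.isin(probe_gene_idx, idx)
        sample_cols = (subset_of.loc[sample_ids] == subset).to_numpy()
        expr[np.ix_(probe_rows, sample_cols)] += spec.expr_effect

    expr_study = ExpressionStudy(
        values=pd.DataFrame(expr, index=expr_probes, columns=sample_ids),
        probe_to_gene=probe_to_gene,
        design=design.copy(),
    )

    # --- methylation --------------------------------------------------
    meth_probes = np.array(
        [f"cg{i + 1:08d}" for i in range(spec.n_probes_meth)]
    )
    # every gene gets at least one probe; the remainder are spread at random
    meth_gene_idx = np.concatenate(
        [
            np.arange(spec.n_genes),
            rng.integers(0, spec.n_genes, spec.n_probes_meth - spec.n_genes),
        ]
    )
    region = rng.choice(
        _REGION_CHOICES, size=spec.n_probes_meth, p=_REGION_WEIGHTS
    )
    design_type = np.where(
        rng.random(spec.n_probes_meth) < 0.28, "I", "II"
    )

    # guarantee every planted gene at least one promoter probe: each
    # gene's first probe (rows 0..n_genes-1 map 1:1) is promotered if the
    # gene carries a signature
    planted_gene_idx = set(sig_gene_idx.tolist())
    first_probe_promoter = ~np.isin(
        region[: spec.n_genes], PROMOTER_REGIONS
    ) & np.isin(np.arange(spec.n_genes), list(planted_gene_idx))
    region[: spec.n_genes][first_probe_promoter] = "TSS1500"

    is_promoter = np.isin(region, PROMOTER_REGIONS)

    # bimodal baseline: unmethylated and methylated modes
    low_mode = rng.random(spec.n_probes_meth) < 0.5
    base_beta = np.where(
        low_mode,
        rng.normal(0.10, 0.03, spec.n_probes_meth),
        rng.normal(0.85, 0.03, spec.n_probes_meth),
    )
    # planted probes start methylated so hypomethylation has room to act
    hypomethylated: dict[str, tuple[str, ...]] = {}
    planted_rows_by_subset: dict[str, np.ndarray] = {}
    for subset in spec.signature_subsets:
        gene_idx = np.flatnonzero(
            np.isin(genes, signature_genes[subset])
        )
        rows = np.isin(meth_gene_idx, gene_idx) & is_promoter
        planted_rows_by_subset[subset] = rows
        hypomethylated[subset] = tuple(meth_probes[rows])
        base_beta[rows] = rng.normal(0.85, 0.02, rows.sum())
    base_beta = np.clip(base_beta, 0.03, 0.97)

    mean_beta = np.repeat(base_beta[:, None], n_samples, axis=1)
    for subset, rows in planted_rows_by_subset.items():
        cols = (subset_of.loc[sample_ids] == subset).to_numpy()
        mean_beta[np.ix_(rows, cols)] = np.clip(
            mean_beta[np.ix_(rows, cols)] + spec.meth_effect, 0.02, 0.98
        )
    # donor random effect: a per-(probe, donor) offset on the M scale,
    # identical across that donor's subsets (cancels in paired tests)
    if spec.donor_effect_sd > 0:
        donors = design["donor"].unique()
        offset = rng.normal(
            0.0, spec.donor_effect_sd, (spec.n_probes_meth, len(donors))
        )
        donor_col = design.set_index("sample_id")["donor"]
        donor_idx = np.array(
            [np.where(donors == donor_col[s])[0][0] for s in sample_ids]
        )
        logit_mean = np.log2(mean_beta / (1.0 - mean_beta))
        logit_mean += offset[:, donor_idx]
        mean_beta = 1.0 / (1.0 + 2.0 ** (-logit_mean))
        mean_beta = np.clip(mean_beta, 0.02, 0.98)
    c = spec.beta_concentration
    beta = rng.beta(mean_beta * c, (1.0 - mean_beta) * c)
    beta = np.clip(beta, 1e-4, 1 - 1e-4)

    # Infinium design bias: compress type-II probes toward 0.5
    ii_rows = design_type == "II"
    beta[ii_rows] = 0.5 + (beta[ii_rows] - 0.5) * (
        1.0 - spec.typeII_compression
    )

    total = rng.lognormal(np.log(8000.0), 0.25, beta.shape)
    raw_m = beta * total
    raw_u = (1.0 - beta) * total

    detection_p = rng.uniform(0.0, 0.01, beta.shape)
    protected = np.zeros(spec.n_probes_meth, dtype=bool)
    for rows in planted_rows_by_subset.values():
        protected |= rows
    fail_probe = (
        rng.random(spec.n_probes_meth) < spec.detection_fail_rate
    ) & ~protected
    fail_sample = rng.integers(0, n_samples, spec.n_probes_meth)
    detection_p[fail_probe, fail_sample[fail_probe]] = rng.uniform(
        0.05, 0.5, int(fail_probe.sum())
    )
    cross_reactive = (
        rng.random(spec.n_probes_meth) < spec.cross_reactive_rate
    ) & ~protected
    snp_overlap = rng.random(spec.n_probes_meth) < spec.snp_overlap_rate

    annotation = pd.DataFrame(
        {
            "gene": np.where(
                region == "intergenic", "", genes[meth_gene_idx]
            ),
            "region": region,
            "design_type": design_type,
            "cross_reactive": cross_reactive,
            "snp_overlap": snp_overlap,
        },
        index=meth_probes,
    )
    meth_study = MethylationStudy(
        beta=pd.DataFrame(beta, index=meth_probes, columns=sample_ids),
        annotation=annotation,
        design=design.copy(),
        raw_m=pd.DataFrame(raw_m, index=meth_probes, columns=sample_ids),
        raw_u=pd.DataFrame(raw_u, index=meth_probes, columns=sample_ids),
        detection_p=pd.DataFrame(
            detection_p, index=meth_probes, columns=sample_ids
        ),
    )
    # intergenic probes lose their gene label but may have been planted;
    # planted rows were restricted to promoter regions so none are intergenic
    truth = GroundTruth(
        signature_genes=signature_genes,
        hypomethylated_probes=hypomethylated,
    )
    return expr_study, meth_study, truth


# ---------------------------------------------------------------------------
# Assay fixtures

_QPCR_SUBSETS = ("CD4_naive", "CM_Th1", "EM28_Th1", "CD4_CTX")

#: planted log2 fold changes vs naive CD4 (stepwise induction of the
#: cytotoxic program along the Th1 lineage)
_QPCR_DEFAULT_EFFECTS = {
    "PRF1": {"CM_Th1": 1.5, "EM28_Th1": 3.0, "CD4_CTX": 5.0},
    "GZMB": {"CM_Th1": 1.0, "EM28_Th1": 2.5, "CD4_CTX": 4.5},
    "RUNX3": {"CM_Th1": 0.5, "EM28_Th1": 1.5, "CD4_CTX": 2.5},
    "TBX21": {"CM_Th1": 1.0, "EM28_Th1": 2.0, "CD4_CTX": 2.5},
}


def make_qpcr_fixture(
    seed: int,
    effects: dict[str, dict[str, float]] | None = None,
    n_donors: int = 5,
    n_replicates: int = 2,
    noise_sd: float = 0.12,
    reference_gene: str = "EEF1A1",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Tidy Cp table with planted log2 fold changes vs naive CD4.

    ``effects[gene][subset]`` is the planted log2 fold change relative
    to the calibrator subset (CD4_naive).  Pass ``effects={}`` for a
    null fixture (all fold changes 1).
    """
    rng = np.random.default_rng(seed)
    effects = _QPCR_DEFAULT_EFFECTS if effects is None else effects
    genes = sorted(set(effects) | {"PRF1"})
    rows = []
    for d in range(n_donors):
        donor = f"D{d + 1}"
        ref_cp = rng.normal(17.0, 0.5)
        for subset in _QPCR_SUBSETS:
            shift = rng.normal(0.0, 0.3)  # pipetting/input offset
            for gene in [reference_gene, *genes]:
                if gene == reference_gene:
                    true_cp = ref_cp + shift
                else:
                    base_dcp = 8.0
                    lfc = effects.get(gene, {}).get(subset, 0.0)
                    true_cp = ref_cp + shift + base_dcp - lfc
                for rep in range(n_replicates):
                    rows.append(
                        {
                            "sample_id": f"{subset}_{donor}",
                            "donor": donor,
                            "subset": subset,
                            "gene": gene,
                            "cp": true_cp + rng.normal(0.0, noise_sd),
                            "replicate": rep + 1,
                        }
                    )
    truth = GroundTruth(
        signature_genes={},
        hypomethylated_probes={},
        assay_effects={"log2_fold_change": effects},
    )
    return pd.DataFrame(rows), truth


_CHIP_REGIONS = ("TSS", "-1kb", "-5.5kb", "-7.7kb", "-15kb")

#: planted %input(target)/%input(H3) enrichment ratios per region
_CHIP_DEFAULT_EFFECTS = {
    "H3K4me3": {"TSS": 4.0, "-1kb": 2.0, "-5.5kb": 1.0, "-7.7kb": 1.0,
                "-15kb": 1.0},
    "H3K27ac": {"TSS": 2.0, "-1kb": 1.5, "-5.5kb": 3.0, "-7.7kb": 3.0,
                "-15kb": 1.0},
}


def make_chip_fixture(
    seed: int,
    effects: dict[str, dict[str, float]] | None = None,
    n_donors: int = 3,
    input_fraction: float = 0.01,
    h3_percent_input: float = 10.0,
    noise_sd: float = 0.08,
) -> tuple[pd.DataFrame, GroundTruth]:
    """ChIP-qPCR Cp table with planted H3-normalized enrichment ratios."""
    rng = np.random.default_rng(seed)
    effects = _CHIP_DEFAULT_EFFECTS if effects is None else effects
    rows = []
    for d in range(n_donors):
        donor = f"D{d + 1}"
        for r_i, region in enumerate(_CHIP_REGIONS):
            cp_input = rng.normal(24.0, 0.4)
            adjusted = cp_input - np.log2(1.0 / input_fraction)
            cp_h3 = adjusted - np.log2(h3_percent_input / 100.0)
            wells = {"input": cp_input, "H3": cp_h3}
            for ab, by_region in effects.items():
                ratio = by_region.get(region, 1.0)
                pct = h3_percent_input * ratio
                wells[ab] = adjusted - np.log2(pct / 100.0)
            for ab, cp in wells.items():
                rows.append(
                    {
                        "sample_id": f"{donor}_{region}",
                        "donor": donor,
                        "region": region,
                        "antibody": ab,
                        "cp": cp + rng.normal(0.0, noise_sd),
                        "replicate": 1,
                    }
                )
    truth = GroundTruth(
        signature_genes={},
        hypomethylated_probes={},
        assay_effects={
            "enrichment_ratio": effects,
            "input_fraction": input_fraction,
        },
    )
    return pd.DataFrame(rows), truth


_SC_SUBSETS = ("CD4_naive", "CM_Th1", "EM28_Th1", "CD4_CTX")

#: planted fraction of PRF1+ cells per subset and, among PRF1+ cells,
#: co-expression probability of each transcription factor
_SC_DEFAULT_ANCHOR = {
    "CD4_naive": 0.05, "CM_Th1": 0.30, "EM28_Th1": 0.55, "CD4_CTX": 0.90,
}
_SC_DEFAULT_PARTNERS = {
    "RUNX3": {"CD4_naive": 0.5, "CM_Th1": 0.6, "EM28_Th1": 0.7,
              "CD4_CTX": 0.9},
    "TBX21": {"CD4_naive": 0.3, "CM_Th1": 0.5, "EM28_Th1": 0.7,
              "CD4_CTX": 0.8},
    "ZBTB7B": {"CD4_naive": 0.9, "CM_Th1": 0.9, "EM28_Th1": 0.9,
               "CD4_CTX": 0.9},
    "EOMES": {"CD4_naive": 0.1, "CM_Th1": 0.3, "EM28_Th1": 0.5,
              "CD4_CTX": 0.7},
}


def make_singlecell_fixture(
    seed: int,
    n_cells: int = 43,
    anchor_fractions: dict[str, float] | None = None,
    partner_coexpression: dict[str, dict[str, float]] | None = None,
    anchor_gene: str = "PRF1",
    housekeeping_gene: str = "EEF1A1",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cells x genes single-cell expression table, 43 cells per subset.

    Positive cells get a log2 expression level drawn around 8; negative
    cells are exactly 0 (below limit of detection).  Partner positivity
    is sampled conditionally on the anchor so the planted
    double-positive/anchor-positive proportions are the values in
    ``partner_coexpression``.
    """
    rng = np.random.default_rng(seed)
    anchors = _SC_DEFAULT_ANCHOR if anchor_fractions is None else anchor_fractions
    partners = (
        _SC_DEFAULT_PARTNERS
        if partner_coexpression is None
        else partner_coexpression
    )
    rows = []
    for subset in _SC_SUBSETS:
        for _ in range(n_cells):
            cell = {"subset": subset}
            cell[housekeeping_gene] = rng.normal(12.0, 0.8)
            anchor_on = rng.random() < anchors.get(subset, 0.0)
            cell[anchor_gene] = rng.normal(8.0, 1.0) if anchor_on else 0.0
            for gene, by_subset in partners.items():
                p_on = by_subset.get(subset, 0.0) if anchor_on else 0.3
                on = rng.random() < p_on
                cell[gene] = rng.normal(8.0, 1.0) if on else 0.0
            rows.append(cell)
    truth = GroundTruth(
        signature_genes={},
        hypomethylated_probes={},
        assay_effects={
            "anchor_fraction": anchors,
            "partner_coexpression": partners,
        },
    )
    return pd.DataFrame(rows), truth


_PYRO_SUBSETS = ("CD4_naive", "CM_Th1", "EM28_Th1", "CD4_CTX")

#: planted per-region methylation % along the differentiation gradient:
#: the distal region stays methylated, the intermediate and proximal
#: regions demethylate stepwise toward the cytotoxic stage
_PYRO_DEFAULT_LEVELS = {
    "CD4_naive": {"distal": 88.0, "intermediate": 90.0, "proximal": 85.0},
    "CM_Th1": {"distal": 85.0, "intermediate": 70.0, "proximal": 60.0},
    "EM28_Th1": {"distal": 84.0, "intermediate": 50.0, "proximal": 40.0},
    "CD4_CTX": {"distal": 82.0, "intermediate": 25.0, "proximal": 15.0},
}

_PYRO_REGION_SITES = {
    "distal": range(1, 16),
    "intermediate": range(16, 29),
    "proximal": range(29, 35),
}


def make_pyroseq_fixture(
    seed: int,
    n_donors: int = 5,
    levels: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 5.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-CpG methylation-% table over the 34 PRF1 promoter sites.

    Rows are (subset, donor) pairs; the 34 columns are CpG sites 1..34
    covered by the 11 pyrosequencing amplicons of the assay design.
    """
    rng = np.random.default_rng(seed)
    levels = _PYRO_DEFAULT_LEVELS if levels is None else levels
    index = pd.MultiIndex.from_product(
        [list(levels), [f"D{d + 1}" for d in range(n_donors)]],
        names=["subset", "donor"],
    )
    site_level = {}
    for subset, by_region in levels.items():
        per_site = np.empty(34)
        for region, sites in _PYRO_REGION_SITES.items():
            for s in sites:
                per_site[s - 1] = by_region[region]
        site_level[subset] = per_site
    data = np.vstack(
        [
            np.clip(
                site_level[subset] + rng.normal(0.0, noise_sd, 34), 0.0, 100.0
            )
            for subset, _ in index
        ]
    )
    table = pd.DataFrame(
        data, index=index, columns=[f"CpG{i}" for i in range(1, 35)]
    )
    truth = GroundTruth(
        signature_genes={},
        hypomethylated_probes={},
        assay_effects={"region_levels": levels},
    )
    return table, truth
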