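import numpy as np
import pandas as pd
import pytest

from tcellsig.methylome import (
    MethylationStudy,
    beta_from_m,
    compute_beta,
    dm_test,
    filter_probes,
    m_values,
    peak_correct,
    promoter_probes,
    region_proportions,
)
from tcellsig.synthetic_data import StudySpec, make_study

from conftest import small_design


def toy_methylation(beta, subsets=("A", "B"), n_donors=None, regions=None,
                    genes=None, types=None, detection_p=None):
    beta = np.asarray(beta, dtype=float)
    n_probes, n_samples = beta.shape
    if n_donors is None:
        n_donors = n_samples // len(subsets)
    design = small_design(subsets, n_donors)
    probes = [f"cg{i:04d}" for i in range(n_probes)]
    ann = pd.DataFrame(
        {
            "gene": genes if genes is not None else [f"G{i}" for i in range(n_probes)],
            "region": regions if regions is not None else ["TSS200"] * n_probes,
            "design_type": types if types is not None else ["II"] * n_probes,
            "cross_reactive": [False] * n_probes,
            "snp_overlap": [False] * n_probes,
        },
        index=probes,
    )
    frame = pd.DataFrame(beta, index=probes, columns=design["sample_id"])
    dp = (
        None
        if detection_p is None
        else pd.DataFrame(detection_p, index=probes, columns=frame.columns)
    )
    return MethylationStudy(
        beta=frame, annotation=ann, design=design, detection_p=dp
    )


class TestBetaAndMValues:
    def test_beta_formula_cases(self):
        m = pd.DataFrame({"s": [30.0, 50.0, 0.0]})
        u = pd.DataFrame({"s": [70.0, 50.0, 10.0]})
        beta = compute_beta(m, u)
        assert beta["s"].tolist() == pytest.approx([0.3, 0.5, 0.0])

    def test_zero_total_signal_is_missing(self):
        beta = compute_beta(
            pd.DataFrame({"s": [0.0]}), pd.DataFrame({"s": [0.0]})
        )
        assert np.isnan(beta["s"].iloc[0])

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(
                pd.DataFrame({"s": [-1.0]}), pd.DataFrame({"s": [1.0]})
            )

    def test_m_value_cases(self):
        beta = pd.DataFrame({"s": [0.5, 0.8, 0.2]})
        m = m_values(beta)
        assert m["s"].tolist() == pytest.approx([0.0, 2.0, -2.0])

    def test_logit_round_trip(self):
        b = np.linspace(0.001, 0.999, 101)
        assert np.allclose(beta_from_m(m_values(b)), b, atol=1e-12)


class TestFilterProbes:
    def make(self):
        rng = np.random.default_rng(0)
        beta = rng.uniform(0.1, 0.9, (6, 6))
        dp = np.full((6, 6), 0.001)
        dp[0, 2] = 0.2  # probe 0 fails detection in one sample
        study = toy_methylation(beta, detection_p=dp)
        study.annotation.loc["cg0001", "cross_reactive"] = True
        study.annotation.loc["cg0002", "snp_overlap"] = True
        return study

    def test_detection_failure_any_sample_removes_probe(self):
        kept, report = filter_probes(self.make())
        assert "cg0000" not in kept.beta.index
        assert report["removed_detection"] == 1

    def test_cross_reactive_removed_snp_retained(self):
        kept, report = filter_probes(self.make())
        assert "cg0001" not in kept.beta.index
        assert "cg0002" in kept.beta.index
        assert report["removed_cross_reactive"] == 1
        assert report["retained_snp_overlap"] == 1

    def test_all_rule_keeps_partially_detected_probe(self):
        kept, _ = filter_probes(self.make(), detection_rule="all")
        assert "cg0000" in kept.beta.index


class TestPeakCorrect:
    def test_compressed_type_ii_peaks_restored(self):
        spec = StudySpec(
            n_probes_expr=50,
            n_probes_meth=3000,
            n_signature_genes=2,
            typeII_compression=0.25,
            donor_effect_sd=0.0,
            seed=3,
        )
        _, meth, _ = make_study(spec)
        corrected = peak_correct(meth)
        is_i = meth.annotation["design_type"] == "I"
        # compare the low/high beta modes of both designs after correction
        for col in corrected.beta.columns[:3]:
            b1 = corrected.beta.loc[is_i, col]
            b2 = corrected.beta.loc[~is_i, col]
            for side in (0.25, 0.75):
                q1 = b1[b1 < 0.5].median() if side == 0.25 else b1[b1 > 0.5].median()
                q2 = b2[b2 < 0.5].median() if side == 0.25 else b2[b2 > 0.5].median()
                assert abs(q1 - q2) < 0.03

    def test_no_bias_correction_close_to_identity(self):
        spec = StudySpec(
            n_probes_expr=50,
            n_probes_meth=3000,
            n_signature_genes=2,
            typeII_compression=0.0,
            donor_effect_sd=0.0,
            seed=4,
        )
        _, meth, _ = make_study(spec)
        corrected = peak_correct(meth)
        delta = (corrected.beta - meth.beta).abs().to_numpy()
        assert delta.max() < 0.04

    def test_all_type_i_study_unchanged(self):
        rng = np.random.default_rng(1)
        beta = rng.uniform(0.05, 0.95, (20, 6))
        study = toy_methylation(beta, types=["I"] * 20)
        corrected = peak_correct(study)
        assert np.array_equal(corrected.beta.values, study.beta.values)

    def test_monotone_and_bounded(self):
        spec = StudySpec(
            n_probes_expr=50,
            n_probes_meth=2000,
            n_signature_genes=2,
            typeII_compression=0.3,
            donor_effect_sd=0.0,
            seed=5,
        )
        _, meth, _ = make_study(spec)
        corrected = peak_correct(meth)
        vals = corrected.beta.to_numpy()
        assert vals.min() > 0.0 and vals.max() < 1.0
        is_ii = (meth.annotation["design_type"] == "II").to_numpy()
        col = meth.beta.columns[0]
        before = meth.beta.loc[is_ii, col].to_numpy()
        after = corrected.beta.loc[is_ii, col].to_numpy()
        order = np.argsort(before)
        assert (np.diff(after[order]) >= -1e-12).all()

    def test_unimodal_sample_left_uncorrected_with_warning(self):
        rng = np.random.default_rng(2)
        beta = np.clip(rng.normal(0.5, 0.02, (200, 6)), 0.01, 0.99)
        types = ["I"] * 100 + ["II"] * 100
        study = toy_methylation(beta, types=types)
        with pytest.warns(UserWarning, match="not bimodal"):
            corrected = peak_correct(study)
        assert np.allclose(corrected.beta.values, study.beta.values)


class TestDmTest:
    def test_identical_subsets_yield_no_calls(self):
        rng = np.random.default_rng(0)
        half = rng.uniform(0.2, 0.8, (30, 3))
        beta = np.column_stack([half, half])  # same values in both subsets
        study = toy_methylation(beta)
        dm = dm_test(study, "A", "B")
        assert not dm["called"].any()
        assert np.allclose(dm["delta_beta"], 0.0)
        assert np.isfinite(dm["p_value"]).all()

    def test_antisymmetric_in_subset_order(self):
        rng = np.random.default_rng(1)
        beta = rng.uniform(0.1, 0.9, (40, 8))
        study = toy_methylation(beta, n_donors=4)
        fwd = dm_test(study, "A", "B")
        rev = dm_test(study, "B", "A")
        assert np.allclose(fwd["delta_beta"], -rev["delta_beta"])
        assert np.allclose(fwd["m_t_statistic"], -rev["m_t_statistic"])
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_planted_low_noise_probe_called(self):
        rng = np.random.default_rng(2)
        n = 50
        test = np.clip(rng.normal(0.55, 0.01, (n, 5)), 0.01, 0.99)
        ref = np.clip(rng.normal(0.85, 0.01, (n, 5)), 0.01, 0.99)
        study = toy_methylation(
            np.column_stack([test, ref]), n_donors=5
        )
        dm = dm_test(study, "A", "B")
        assert dm["called"].mean() > 0.95
        assert (dm["delta_beta"] < -0.25).all()

    def test_large_delta_with_weak_p_not_called(self):
        # huge spread across donors: |delta beta| > 0.1 but p >> 1e-4
        beta = np.array(
            [[0.9, 0.1, 0.9, 0.1, 0.9, 0.3, 0.5, 0.4, 0.6, 0.5]]
        )
        study = toy_methylation(beta, n_donors=5)
        dm = dm_test(study, "A", "B")
        assert abs(dm["delta_beta"].iloc[0]) > 0.1
        assert dm["p_value"].iloc[0] > 1e-4
        assert not dm["called"].iloc[0]

    def test_unpaired_donors_rejected(self):
        rng = np.random.default_rng(3)
        design = pd.DataFrame(
            {
                "sample_id": ["A_D1", "A_D2", "A_D3", "A_D4", "B_D1", "B_D2", "B_D3", "B_D5"],
                "subset": ["A"] * 4 + ["B"] * 4,
                "donor": ["D1", "D2", "D3", "D4", "D1", "D2", "D3", "D5"],
            }
        )
        beta = pd.DataFrame(
            rng.uniform(0.2, 0.8, (5, 8)),
            index=[f"cg{i}" for i in range(5)],
            columns=design["sample_id"],
        )
        ann = pd.DataFrame(
            {
                "gene": ["G"] * 5,
                "region": ["TSS200"] * 5,
                "design_type": ["II"] * 5,
                "cross_reactive": [False] * 5,
                "snp_overlap": [False] * 5,
            },
            index=beta.index,
        )
        study = MethylationStudy(beta=beta, annotation=ann, design=design)
        with pytest.raises(ValueError, match="D4.*D5|D5.*D4"):
            dm_test(study, "A", "B")


class TestPromoterAnnotation:
    def make(self):
        regions = ["TSS200", "Body", "TSS1500", "TSS1500", "TSS1500", "3'UTR"]
        genes = ["X", "X", "X", "X", "X", "Y"]
        beta = np.full((6, 6), 0.5)
        return toy_methylation(beta, regions=regions, genes=genes)

    def test_only_promoter_regions_returned(self):
        study = self.make()
        probes = promoter_probes(study, "X")
        assert probes == ["cg0000", "cg0002", "cg0003", "cg0004"]

    def test_unknown_gene_empty(self):
        assert promoter_probes(self.make(), "nope") == []

    def test_region_proportions_counts(self):
        props = region_proportions(self.make(), "X")
        assert props["TSS1500"] == pytest.approx(0.75)
        assert props["TSS200"] == pytest.approx(0.25)
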