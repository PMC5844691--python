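import numpy as np
import pytest

from tcellsig.io_formats import GeneSet, RankedList
from tcellsig.gsea import (
    GseaConfig,
    enrichment_score,
    gsea_preranked,
    gsea_run,
    nondifferential_geneset,
    rank_by_metric,
)

from conftest import toy_expression


def ks_walk_oracle(ids, scores, members, p):
    """Independent brute-force KS walk: explicit python loop, no shortcuts.

    Positive/negative magnitude ties resolve to the positive side, the
    documented convention.
    """
    members = set(members)
    n = len(ids)
    hits = [i for i, g in enumerate(ids) if g in members]
    k = len(hits)
    weights = [abs(s) ** p for s in scores]
    denom = sum(weights[i] for i in hits)
    running = 0.0
    hi, lo = -np.inf, np.inf
    for i in range(n):
        if i in set(hits):
            running += (weights[i] / denom) if denom > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        hi, lo = max(hi, running), min(lo, running)
    return hi if hi >= -lo else lo


def make_ranked(scores):
    ids = tuple(f"g{i:03d}" for i in range(len(scores)))
    return RankedList(ids, tuple(float(s) for s in scores))


class TestEnrichmentScore:
    def test_top_gene_unweighted_is_one(self):
        rl = make_ranked([4.0, 3.0, 2.0, 1.0])
        es, prof = enrichment_score(rl, GeneSet("s", "", (rl.ids[0],)), 0.0)
        assert es == pytest.approx(1.0)
        assert len(prof) == 4

    def test_bottom_gene_unweighted_is_minus_one(self):
        rl = make_ranked([4.0, 3.0, 2.0, 1.0])
        es, prof = enrichment_score(rl, GeneSet("s", "", (rl.ids[-1],)), 0.0)
        assert es == pytest.approx(-1.0)
        assert prof[2] == pytest.approx(-1.0)

    def test_equal_scores_weighting_irrelevant(self):
        rl = make_ranked([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        gs = GeneSet("s", "", (rl.ids[1], rl.ids[4]))
        es0, _ = enrichment_score(rl, gs, 0.0)
        es1, _ = enrichment_score(rl, gs, 1.0)
        assert es0 == pytest.approx(es1)

    def test_exhaustive_four_gene_configurations(self):
        # every non-trivial gene set over a 4-gene list, both exponents
        rng = np.random.default_rng(0)
        scores = sorted(rng.normal(0, 2, 4), reverse=True)
        rl = make_ranked(scores)
        for mask in range(1, 15):  # proper non-empty subsets
            members = tuple(
                rl.ids[i] for i in range(4) if mask & (1 << i)
            )
            for p in (0.0, 1.0):
                es, _ = enrichment_score(rl, GeneSet("s", "", members), p)
                want = ks_walk_oracle(rl.ids, rl.scores, members, p)
                assert es == pytest.approx(want, abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(5, 200))
            k = int(rng.integers(1, n))
            rl = make_ranked(np.sort(rng.normal(0, 2, n))[::-1])
            members = tuple(np.random.default_rng(0).choice(rl.ids, k, replace=False))
            p = float(rng.choice([0.0, 1.0]))
            es, _ = enrichment_score(rl, GeneSet("s", "", members), p)
            want = ks_walk_oracle(rl.ids, rl.scores, members, p)
            assert es == pytest.approx(want, abs=1e-12)

    def test_bounded_and_profile_length(self):
        rng = np.random.default_rng(2)
        rl = make_ranked(np.sort(rng.normal(0, 1, 60))[::-1])
        gs = GeneSet("s", "", tuple(rl.ids[5:20]))
        es, prof = enrichment_score(rl, gs, 1.0)
        assert -1.0 <= es <= 1.0
        assert len(prof) == 60

    def test_disjoint_set_rejected(self):
        rl = make_ranked([1.0, 0.5])
        with pytest.raises(ValueError, match="no members"):
            enrichment_score(rl, GeneSet("s", "", ("absent",)), 1.0)

    def test_matches_external_reference_implementation(self):
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rnk = pd.Series(
            np.linspace(5, -5, 50), index=[f"g{i}" for i in range(50)]
        )
        members = [f"g{i}" for i in (1, 3, 5, 7, 20, 33)]
        res = gseapy.prerank(
            rnk=rnk,
            gene_sets={"S": members},
            permutation_num=4,
            seed=1,
            outdir=None,
            min_size=1,
            max_size=500,
            weight=1.0,
            no_plot=True,
        )
        rl = RankedList(tuple(rnk.index), tuple(rnk.values))
        es, _ = enrichment_score(rl, GeneSet("S", "", tuple(members)), 1.0)
        assert es == pytest.approx(float(res.res2d["ES"].iloc[0]), abs=1e-6)


class TestRankByMetric:
    def make_study(self):
        # 5 genes, hand-set class means
        a = np.array(
            [[6.0, 6.0], [4.0, 4.0], [5.0, 7.0], [2.0, 2.0], [8.0, 8.0]]
        )
        b = np.array(
            [[6.0, 6.0], [5.0, 5.0], [4.0, 4.0], [5.0, 5.0], [1.0, 1.0]]
        )
        return toy_expression(
            np.column_stack([a, b]), subsets=("A", "B"), n_donors=2
        )

    def test_scores_equal_difference_of_means(self):
        rl = rank_by_metric(self.make_study(), "A", "B")
        scores = rl.to_series()
        assert scores["G4"] == pytest.approx(7.0)
        assert scores["G0"] == pytest.approx(0.0)
        assert scores["G3"] == pytest.approx(-3.0)

    def test_antisymmetric_under_class_swap(self):
        st = self.make_study()
        fwd = rank_by_metric(st, "A", "B").to_series()
        rev = rank_by_metric(st, "B", "A").to_series()
        assert np.allclose(fwd.sort_index(), -rev.sort_index())

    def test_empty_class_rejected(self):
        with pytest.raises(KeyError):
            rank_by_metric(self.make_study(), "A", "missing")


class TestGseaPermutation:
    def ranked(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        return make_ranked(np.sort(rng.normal(0, 1.5, n))[::-1])

    def test_deterministic_under_fixed_seed(self):
        rl = self.ranked()
        sets = [
            GeneSet("top", "", tuple(rl.ids[:12])),
            GeneSet("spread", "", tuple(rl.ids[::10])),
        ]
        cfg = GseaConfig(n_perm=50, seed=42)
        r1 = gsea_preranked(rl, sets, cfg)
        r2 = gsea_preranked(rl, sets, cfg)
        assert [(a.nes, a.fdr, a.nominal_p) for a in r1] == [
            (a.nes, a.fdr, a.nominal_p) for a in r2
        ]

    def test_results_independent_of_geneset_order(self):
        rl = self.ranked()
        s1 = GeneSet("top", "", tuple(rl.ids[:12]))
        s2 = GeneSet("bottom", "", tuple(rl.ids[-12:]))
        cfg = GseaConfig(n_perm=50, seed=3)
        # the permutation stream is keyed on the set's position, so the
        # per-set ES and nominal p must not depend on companions
        r_a = {r.geneset_name: r.es for r in gsea_preranked(rl, [s1, s2], cfg)}
        r_b = {r.geneset_name: r.es for r in gsea_preranked(rl, [s2, s1], cfg)}
        assert r_a == r_b

    def test_planted_top_set_is_significant(self):
        rl = self.ranked()
        planted = GeneSet("top", "", tuple(rl.ids[:15]))
        decoys = [
            GeneSet(f"d{i}", "", tuple(
                np.random.default_rng(i).choice(rl.ids, 15, replace=False)
            ))
            for i in range(20)
        ]
        res = gsea_preranked(rl, [planted, *decoys], GseaConfig(n_perm=200, seed=1))
        top = next(r for r in res if r.geneset_name == "top")
        assert top.es > 0.8
        assert top.fdr < 0.25
        assert top.nominal_p < 0.05

    def test_reversed_ranking_negates_unweighted_es(self):
        rl = self.ranked()
        rev = RankedList(rl.ids, tuple(-s for s in rl.scores))
        gs = GeneSet("s", "", tuple(rl.ids[3:20]))
        cfg = GseaConfig(n_perm=10, seed=0, weight_exponent=0.0)
        es_fwd = next(iter(gsea_preranked(rl, [gs], cfg))).es
        es_rev = next(iter(gsea_preranked(rev, [gs], cfg))).es
        assert es_fwd == pytest.approx(-es_rev, abs=1e-9)

    def test_single_permutation_degenerate_but_finite(self):
        rl = self.ranked(n=30)
        gs = GeneSet("s", "", tuple(rl.ids[:5]))
        (res,) = gsea_preranked(rl, [gs], GseaConfig(n_perm=1, seed=0))
        assert np.isfinite(res.fdr)
        assert 0.0 <= res.nominal_p <= 1.0

    def test_empty_geneset_list_gives_empty_result(self):
        assert gsea_preranked(self.ranked(), [], GseaConfig(n_perm=5)) == []

    def test_oversized_geneset_skipped_with_warning(self):
        rl = make_ranked([3.0, 2.0, 1.0])
        gs = GeneSet("all", "", tuple(rl.ids))
        with pytest.warns(UserWarning, match="skipping"):
            res = gsea_preranked(rl, [gs], GseaConfig(n_perm=5))
        assert res == []

    def test_leading_edge_members_are_set_members(self):
        rl = self.ranked()
        gs = GeneSet("s", "", tuple(rl.ids[:10]))
        (res,) = gsea_preranked(rl, [gs], GseaConfig(n_perm=20, seed=0))
        assert set(res.leading_edge) <= set(gs.genes)
        assert res.leading_edge  # a strongly positive set has a leading edge


class TestGseaRun:
    def test_two_class_mode_consistent_with_preranked(self, planted_study):
        expr, _, truth = planted_study
        sig = GeneSet("planted", "", truth.signature_genes["CD4_CTX"])
        cfg = GseaConfig(n_perm=100, seed=7)
        via_run = gsea_run(expr, "CD4_CTX", "CD4_naive", [sig], cfg)
        ranked = rank_by_metric(expr, "CD4_CTX", "CD4_naive")
        via_pre = gsea_preranked(ranked, [sig], cfg)
        assert via_run[0].es == pytest.approx(via_pre[0].es)
        assert via_run[0].fdr == via_pre[0].fdr

    def test_planted_signature_enriched_in_its_subset(self, planted_study):
        expr, _, truth = planted_study
        sig = GeneSet("planted", "", truth.signature_genes["CD4_CTX"])
        res = gsea_run(
            expr, "CD4_CTX", "CD4_naive", [sig], GseaConfig(n_perm=200, seed=1)
        )
        assert res[0].es > 0
        assert res[0].fdr < 0.25

    def test_nondifferential_control_helper(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(8, 0.01, (50, 6))
        vals[:10, :3] += 2.0  # strongly differential block
        study = toy_expression(vals, subsets=("A", "B"), n_donors=3)
        ctl = nondifferential_geneset(study, "A", "B", max_abs_diff=0.1)
        assert len(ctl) == 40
        assert not ({f"G{i}" for i in range(10)} & set(ctl.genes))
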