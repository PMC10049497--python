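import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mecp2core import enrichment as en
from mecp2core.enrichment import RankedList

from conftest import make_contrast


def ranked(genes, scores):
    return RankedList(pd.DataFrame({"gene": genes, "score": scores}))


class TestRankGenes:
    def test_score_formula(self):
        t = make_contrast("c", [("g1", 2.0, 0.01)])
        assert en.rank_genes(t).scores[0] == pytest.approx(4.0)

    def test_fdr_one_gives_zero(self):
        t = make_contrast("c", [("g1", 5.0, 1.0)])
        assert en.rank_genes(t).scores[0] == 0.0

    def test_zero_fdr_clamped_finite(self):
        t = make_contrast("c", [("g1", 1.0, 0.0)])
        s = en.rank_genes(t, pseudocount=1e-300).scores[0]
        assert np.isfinite(s) and s == pytest.approx(300.0)

    def test_sorted_descending_with_gene_tiebreak(self):
        t = make_contrast("c", [("b", 1.0, 0.1), ("a", 1.0, 0.1), ("z", 2.0, 0.1)])
        assert en.rank_genes(t).genes == ["z", "a", "b"]


class TestInvertScores:
    def test_negation_and_resort(self):
        r = ranked(["a", "b"], [3.0, -1.0])
        out = en.invert_scores(r)
        assert out.scores.tolist() == [1.0, -3.0] and out.genes == ["b", "a"]

    def test_double_inversion_identity(self):
        r = ranked(list("abc"), [3.0, 1.0, -2.0])
        back = en.invert_scores(en.invert_scores(r))
        pd.testing.assert_frame_equal(back.data, r.data)

    def test_flips_es_sign(self):
        rng = np.random.default_rng(1)
        r = ranked([f"g{i}" for i in range(50)], rng.normal(size=50))
        s = {f"g{i}" for i in range(0, 50, 7)}
        es1, _ = en.enrichment_score(r, s)
        es2, _ = en.enrichment_score(en.invert_scores(r), s)
        assert es1 == pytest.approx(-es2, abs=1e-9)


class TestEnrichmentScore:
    def test_top_gene_singleton_is_one(self):
        r = ranked(list("abcde"), [5.0, 4.0, 3.0, 2.0, 1.0])
        es, _ = en.enrichment_score(r, {"a"}, weight=1.0)
        assert es == pytest.approx(1.0)

    def test_hand_walked_five_gene_example(self):
        """Scores 5..1, hits at ranks 1 and 3, weight 1: running sum is
        5/8, 5/8-1/3, 5/8+3/8-1/3, ... with maximum 2/3."""
        r = ranked(list("abcde"), [5.0, 4.0, 3.0, 2.0, 1.0])
        es, running = en.enrichment_score(r, {"a", "c"}, weight=1.0)
        expected = [5 / 8, 5 / 8 - 1 / 3, 1 - 1 / 3, 1 - 2 / 3, 0.0]
        np.testing.assert_allclose(running, expected, atol=1e-12)
        assert es == pytest.approx(2 / 3)

    def test_running_sum_terminates_at_zero(self):
        rng = np.random.default_rng(5)
        r = ranked([f"g{i}" for i in range(200)], rng.normal(size=200))
        for k in (1, 5, 50):
            _, running = en.enrichment_score(r, {f"g{i}" for i in range(0, 200, 200 // k)})
            assert abs(running[-1]) < 1e-9

    def test_es_bounded(self):
        rng = np.random.default_rng(6)
        r = ranked([f"g{i}" for i in range(100)], rng.normal(size=100))
        for seed in range(10):
            s = set(np.random.default_rng(seed).choice(r.genes, 10, replace=False))
            es, _ = en.enrichment_score(r, s)
            assert -1.0 <= es <= 1.0

    def test_empty_intersection_errors(self):
        r = ranked(["a"], [1.0])
        with pytest.raises(ValueError):
            en.enrichment_score(r, {"zz"})

    def test_full_coverage_errors(self):
        r = ranked(["a", "b"], [1.0, 2.0])
        with pytest.raises(ValueError):
            en.enrichment_score(r, {"a", "b"})


class TestPermutationEnrichment:
    def test_p_floor(self):
        # a set of the 5 top-ranked genes on a steep ranking: no null as extreme
        scores = np.concatenate([[100, 90, 80, 70, 60], np.zeros(195)])
        r = ranked([f"g{i}" for i in range(200)], scores)
        (res,) = en.permutation_enrichment(r, {"top": {"g0", "g1", "g2", "g3", "g4"}},
                                           n_perm=1000, seed=4)
        assert res.pvalue >= 1 / 1001
        assert res.es > 0 and np.sign(res.nes) == np.sign(res.es)

    def test_planted_core_enriched(self, default_multi_contrast):
        """A concordant contrast is positively enriched in the planted up
        core and negatively in the down core."""
        tables, _, truth = default_multi_contrast
        r = en.rank_genes(tables[0])
        res = {
            x.gene_set_name: x
            for x in en.permutation_enrichment(
                r, {"up": truth.core_up, "down": truth.core_down}, n_perm=500, seed=2
            )
        }
        assert res["up"].es > 0 and res["up"].pvalue <= 0.01
        assert res["down"].es < 0 and res["down"].pvalue <= 0.01

    def test_null_calibration(self):
        rng = np.random.default_rng(77)
        genes = [f"g{i}" for i in range(500)]
        r = ranked(genes, rng.normal(size=500))
        sets = {f"s{j}": set(rng.choice(genes, 50, replace=False)) for j in range(100)}
        ps = np.array([x.pvalue for x in en.permutation_enrichment(r, sets, n_perm=200, seed=8)])
        assert 0.01 <= np.mean(ps <= 0.05) <= 0.10

    def test_matches_exhaustive_null_on_tiny_list(self):
        """MC p within binomial error of the exhaustive gene-permutation p."""
        r = ranked(list("abcdefg"), [7.0, 5.0, 4.0, 3.0, 2.0, 1.5, 1.0])
        target = {"a", "c", "f"}
        (res,) = en.permutation_enrichment(r, {"s": target}, n_perm=2000, seed=3)
        obs_es, _ = en.enrichment_score(r, target)
        same_sign, extreme = 0, 0
        for combo in itertools.combinations(r.genes, 3):
            es, _ = en.enrichment_score(r, set(combo))
            if (es >= 0) == (obs_es >= 0):
                same_sign += 1
                extreme += abs(es) >= abs(obs_es)
        p_exact = extreme / same_sign
        mc_sd = math.sqrt(p_exact * (1 - p_exact) / 2000)
        assert abs(res.pvalue - p_exact) <= 4 * mc_sd + 1 / 2000

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        r = ranked([f"g{i}" for i in range(100)], rng.normal(size=100))
        sets = {"s": {f"g{i}" for i in range(0, 100, 9)}}
        a = en.permutation_enrichment(r, sets, n_perm=200, seed=5)
        b = en.permutation_enrichment(r, sets, n_perm=200, seed=5)
        assert a[0].pvalue == b[0].pvalue and a[0].nes == b[0].nes


def exhaustive_hypergeom_upper(M, nA, nB, a):
    tot = math.comb(M, nB)
    return sum(
        math.comb(nA, k) * math.comb(M - nA, nB - k)
        for k in range(a, min(nA, nB) + 1)
    ) / tot


def exhaustive_fisher_two_sided(M, nA, nB, a):
    tot = math.comb(M, nB)
    p_obs = math.comb(nA, a) * math.comb(M - nA, nB - a) / tot
    p = 0.0
    for k in range(max(0, nA + nB - M), min(nA, nB) + 1):
        pk = math.comb(nA, k) * math.comb(M - nA, nB - k) / tot
        if pk <= p_obs * (1 + 1e-7):  # scipy's tie tolerance
            p += pk
    return min(p, 1.0)


class TestOverlap:
    def test_identical_five_gene_sets_in_universe_ten(self):
        u = {f"g{i}" for i in range(10)}
        a = {f"g{i}" for i in range(5)}
        res = en.overlap_test(a, a, u)
        assert res.p_hypergeom == pytest.approx(1 / 252)

    def test_disjoint_cover_odds_zero(self):
        u = {f"g{i}" for i in range(10)}
        a = {f"g{i}" for i in range(5)}
        res = en.overlap_test(a, u - a, u)
        assert res.odds_ratio == 0.0

    def test_b_equals_universe_certain(self):
        u = {f"g{i}" for i in range(8)}
        a = {f"g{i}" for i in range(3)}
        res = en.overlap_test(a, u, u)
        assert res.n_overlap == 3 and res.p_hypergeom == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            en.overlap_test(set(), set(), set())

    def test_agrees_with_enumeration_small_universes(self):
        """Fisher and hypergeometric p match exhaustive enumeration for a
        sweep of 2x2 tables on universes up to 20."""
        genes = [f"g{i}" for i in range(20)]
        for M in range(2, 21, 3):
            u = set(genes[:M])
            for nA in range(0, M + 1, max(1, M // 3)):
                for nB in range(1, M + 1, max(1, M // 3)):
                    for a in range(max(0, nA + nB - M), min(nA, nB) + 1):
                        setA = set(genes[:nA])
                        setB = set(genes[:a]) | set(genes[nA : nA + nB - a])
                        res = en.overlap_test(setA, setB, u)
                        assert res.p_hypergeom == pytest.approx(
                            exhaustive_hypergeom_upper(M, nA, nB, a), rel=1e-9
                        )
                        assert res.p_fisher == pytest.approx(
                            exhaustive_fisher_two_sided(M, nA, nB, a), rel=1e-7
                        )


class TestDirectionalOverlap:
    def make_core(self, up, down):
        from mecp2core.core import CoreResult

        genes = sorted(up | down)
        return CoreResult(
            core_genes=set(genes),
            support=pd.Series(5, index=genes),
            mean_lfc=pd.Series([1.0 if g in up else -1.0 for g in genes], index=genes),
            direction=pd.Series(["up" if g in up else "down" for g in genes], index=genes),
        )

    def test_concordant_contrast(self):
        universe = {f"g{i}" for i in range(20)}
        up = {"g0", "g1"}
        down = {"g2", "g3"}
        core = self.make_core(up, down)
        rows = [(g, 1.0, 0.001) for g in up] + [(g, -1.0, 0.001) for g in down]
        rows += [(f"g{i}", 0.0, 0.9) for i in range(4, 20)]
        t = make_contrast("c", rows)
        res = en.directional_overlap(t, core, alpha=0.01, universe=universe)
        assert res["up_only"].n_overlap == 2
        assert res["down_only"].n_overlap == 2
        assert res["both"].n_overlap == 4

    def test_inverted_contrast_zero_directional(self):
        universe = {f"g{i}" for i in range(20)}
        core = self.make_core({"g0", "g1"}, {"g2", "g3"})
        rows = [("g0", -1.0, 0.001), ("g1", -1.0, 0.001),
                ("g2", 1.0, 0.001), ("g3", 1.0, 0.001)]
        rows += [(f"g{i}", 0.0, 0.9) for i in range(4, 20)]
        t = make_contrast("c", rows)
        res = en.directional_overlap(t, core, alpha=0.01, universe=universe)
        assert res["up_only"].n_overlap == 0
        assert res["down_only"].n_overlap == 0
        assert res["both"].n_overlap == 4

    def test_synthetic_shared_core_significant(self, default_multi_contrast):
        """A contrast sharing the core with concordant sign overlaps
        significantly in all three strata."""
        tables, _, truth = default_multi_contrast
        from mecp2core import core as core_mod

        cfg = core_mod.ConsensusConfig(alpha=0.01, min_contrasts=4,
                                       invert_ids=frozenset(truth.inverted_contrasts))
        _, res = core_mod.run_core_pipeline(tables, cfg)
        universe = set(tables[0].genes)
        out = en.directional_overlap(tables[0], res, alpha=0.01, universe=universe)
        assert out["both"].p_fisher <= 0.05
        assert out["up_only"].p_fisher <= 0.05
        assert out["down_only"].p_fisher <= 0.05
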