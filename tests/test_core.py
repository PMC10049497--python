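import numpy as np
import pandas as pd
import pytest

from mecp2core import core, io
from mecp2core.core import ConsensusConfig, FCMatrix

from conftest import make_contrast


class TestConfig:
    def test_fraction_reproduces_four_of_43(self):
        cfg = ConsensusConfig(alpha=0.01, min_contrasts=None, min_fraction=0.10)
        assert cfg.support_threshold(43) == 4

    def test_fraction_floor_at_one(self):
        cfg = ConsensusConfig(alpha=0.01, min_contrasts=None, min_fraction=0.10)
        assert cfg.support_threshold(3) == 1

    def test_exactly_one_threshold_required(self):
        with pytest.raises(ValueError):
            ConsensusConfig(alpha=0.01, min_contrasts=4, min_fraction=0.1)
        with pytest.raises(ValueError):
            ConsensusConfig(alpha=0.01, min_contrasts=None, min_fraction=None)


class TestBuildFCMatrix:
    def test_masking_rules(self, consensus_cfg):
        t = make_contrast("c1", [("g1", 0.8, 0.005), ("g2", 0.8, 0.02)])
        m = core.build_fc_matrix([t], consensus_cfg)
        df = m.to_frame()
        assert df.loc["g1", "c1"] == 0.8  # passes the mask
        assert df.loc["g2", "c1"] == 0.0  # fdr 0.02 > alpha 0.01

    def test_absent_gene_is_zero(self, consensus_cfg):
        t1 = make_contrast("c1", [("g1", 0.8, 0.005)])
        t2 = make_contrast("c2", [("g2", -0.5, 0.005)])
        df = core.build_fc_matrix([t1, t2], consensus_cfg).to_frame()
        assert df.loc["g1", "c2"] == 0.0 and df.loc["g2", "c1"] == 0.0

    def test_drop_empty_contrasts(self, consensus_cfg):
        tables = [
            make_contrast("c1", [("g1", 0.8, 0.005)]),
            make_contrast("c2", [("g1", 0.8, 0.5)]),
        ]
        m = core.drop_empty_contrasts(core.build_fc_matrix(tables, consensus_cfg))
        assert m.contrasts == ["c1"]

    def test_all_empty_errors(self, consensus_cfg):
        tables = [make_contrast("c1", [("g1", 0.8, 0.5)])]
        with pytest.raises(ValueError):
            core.drop_empty_contrasts(core.build_fc_matrix(tables, consensus_cfg))


class TestInversion:
    def setup_method(self):
        self.m = FCMatrix(
            genes=["g1", "g2", "g3"],
            contrasts=["c1", "c2"],
            masked_lfc=np.array([[0.5, 0.1], [-0.2, 0.0], [0.0, -0.3]]),
        )

    def test_negates_listed_columns_only(self):
        out = core.invert_gain_of_function(self.m, {"c1"})
        np.testing.assert_array_equal(out.masked_lfc[:, 0], [-0.5, 0.2, 0.0])
        np.testing.assert_array_equal(out.masked_lfc[:, 1], self.m.masked_lfc[:, 1])

    def test_involution(self):
        twice = core.invert_gain_of_function(
            core.invert_gain_of_function(self.m, {"c1"}), {"c1"}
        )
        np.testing.assert_array_equal(twice.masked_lfc, self.m.masked_lfc)

    def test_empty_set_identity(self):
        out = core.invert_gain_of_function(self.m, set())
        np.testing.assert_array_equal(out.masked_lfc, self.m.masked_lfc)

    def test_unknown_id_errors(self):
        with pytest.raises(ValueError):
            core.invert_gain_of_function(self.m, {"nope"})


class TestIdentifyCore:
    def test_boundary_inclusive_at_k(self):
        # support exactly 4 of 40 is in; 3 of 40 is out
        mat = np.zeros((2, 40))
        mat[0, :4] = 0.5
        mat[1, :3] = 0.5
        m = FCMatrix(genes=["in4", "in3"], contrasts=[f"c{i}" for i in range(40)], masked_lfc=mat)
        res = core.identify_core(m, ConsensusConfig(alpha=0.01, min_contrasts=4))
        assert res.core_genes == {"in4"}

    def test_six_gene_fixture_recovers_planted(self, six_gene_fixture, consensus_cfg):
        m, res = core.run_core_pipeline(six_gene_fixture, consensus_cfg)
        assert res.core_genes == {"gA", "gB"}
        assert res.direction["gA"] == "up" and res.direction["gB"] == "down"
        assert res.support["gA"] == 8 and res.support["gC"] == 3

    def test_mean_lfc_over_significant_entries_only(self):
        mat = np.array([[0.4, 0.8, 0.0, 0.0]])
        m = FCMatrix(genes=["g"], contrasts=list("abcd"), masked_lfc=mat)
        res = core.identify_core(m, ConsensusConfig(alpha=0.01, min_contrasts=2))
        assert res.mean_lfc["g"] == pytest.approx(0.6)  # not 0.3

    def test_up_down_partition(self, six_gene_fixture, consensus_cfg):
        _, res = core.run_core_pipeline(six_gene_fixture, consensus_cfg)
        assert len(res.core_up) + len(res.core_down) == len(res.core_genes)

    def test_order_invariance(self, six_gene_fixture, consensus_cfg):
        _, res1 = core.run_core_pipeline(six_gene_fixture, consensus_cfg)
        _, res2 = core.run_core_pipeline(six_gene_fixture[::-1], consensus_cfg)
        assert res1.core_genes == res2.core_genes
        pd.testing.assert_series_equal(
            res1.support.sort_index(), res2.support.sort_index()
        )
        pd.testing.assert_series_equal(
            res1.direction.sort_index(), res2.direction.sort_index()
        )


class TestConcordance:
    def test_count_ratio(self):
        mat = np.array([[0.1, 0.2, 0.3, -0.4]])
        m = FCMatrix(genes=["g"], contrasts=list("abcd"), masked_lfc=mat)
        assert core.concordance_profile(m)["g"] == pytest.approx(0.75)

    def test_extremes_and_undefined(self):
        mat = np.array([[0.1, 0.2], [0.0, 0.0]])
        m = FCMatrix(genes=["up", "none"], contrasts=list("ab"), masked_lfc=mat)
        prof = core.concordance_profile(m)
        assert prof["up"] == 1.0 and np.isnan(prof["none"])


class TestGrid:
    def test_six_gene_fixture_sweep(self, six_gene_fixture):
        # hand enumeration of supports: {gA:8, gB:8, gC:3, gD:2, gE:1, gF:1}
        grid = core.grid_core_counts(six_gene_fixture, alphas=[0.01], ks=[1, 4, 9])
        counts = dict(zip(grid["k"], grid["n_core"]))
        assert counts == {1: 6, 4: 2, 9: 0}

    def test_single_contrast_k1(self):
        t = make_contrast("c1", [("g1", 0.5, 0.005), ("g2", -0.5, 0.005), ("g3", 0.1, 0.9)])
        grid = core.grid_core_counts([t], alphas=[0.01], ks=[1])
        assert grid.loc[0, "n_core"] == 2

    def test_k_exceeding_contrasts_gives_zero(self, six_gene_fixture):
        grid = core.grid_core_counts(six_gene_fixture, alphas=[0.01], ks=[11])
        assert grid["n_core"].iloc[0] == 0

    def test_monotone_in_k_and_alpha(self, default_multi_contrast):
        tables, _, truth = default_multi_contrast
        grid = core.grid_core_counts(
            tables, alphas=[0.1, 0.05, 0.01], ks=[1, 4, 12, 20],
            invert_ids=truth.inverted_contrasts,
        )
        for alpha, sub in grid.groupby("alpha"):
            sizes = sub.sort_values("k")["n_core"].to_numpy()
            assert (np.diff(sizes) <= 0).all()
        for k, sub in grid.groupby("k"):
            sizes = sub.sort_values("alpha")["n_core"].to_numpy()
            assert (np.diff(sizes) >= 0).all()  # larger alpha, larger core
        assert (grid["n_up"] + grid["n_down"] == grid["n_core"]).all()


class TestSubgroup:
    def test_fraction_threshold_on_subset(self, six_gene_fixture):
        meta = [
            io.ContrastMetadata(
                contrast_id=f"C{c:02d}",
                study_id="s",
                tissue="cortex",
                cell_fraction="nucleus" if c <= 3 else "whole_cell",
                sex="male",
                species="mouse",
                model_class="loss_of_function",
                n_case=3,
                n_control=3,
            )
            for c in range(1, 11)
        ]
        cfg = ConsensusConfig(alpha=0.01, min_contrasts=None, min_fraction=0.10)
        res = core.subgroup_core(six_gene_fixture, meta, "cell_fraction", "nucleus", cfg)
        # 3 nucleus contrasts, k = 1: genes significant in contrasts 1-3
        assert res.core_genes == {"gA", "gB", "gC", "gD", "gE", "gF"}

    def test_no_match_errors(self, six_gene_fixture):
        with pytest.raises(ValueError):
            core.subgroup_core(six_gene_fixture, [], "tissue", "liver",
                               ConsensusConfig(alpha=0.01, min_contrasts=1))

    def test_full_set_subgroup_equals_identify_core(self, six_gene_fixture, consensus_cfg):
        meta = [
            io.ContrastMetadata(
                contrast_id=t.contrast_id, study_id="s", tissue="cortex",
                cell_fraction="nucleus", sex="male", species="mouse",
                model_class="loss_of_function", n_case=3, n_control=3,
            )
            for t in six_gene_fixture
        ]
        sub = core.subgroup_core(six_gene_fixture, meta, "tissue", "cortex", consensus_cfg)
        _, full = core.run_core_pipeline(six_gene_fixture, consensus_cfg)
        assert sub.core_genes == full.core_genes


class TestRecovery:
    def test_planted_core_recovered(self, default_multi_contrast):
        """Precision/recall/direction against the planted truth at the
        study operating point (FDR 0.01, support >= 4)."""
        tables, _, truth = default_multi_contrast
        cfg = ConsensusConfig(alpha=0.01, min_contrasts=4,
                              invert_ids=frozenset(truth.inverted_contrasts))
        _, res = core.run_core_pipeline(tables, cfg)
        planted = truth.core_up | truth.core_down
        tp = res.core_genes & planted
        assert len(tp) / len(res.core_genes) >= 0.95  # precision
        assert len(tp) / len(planted) >= 0.90  # recall
        correct = sum(
            (res.direction[g] == "up") == (g in truth.core_up) for g in tp
        )
        assert correct / len(tp) >= 0.98

    def test_noiseless_limit_exact(self):
        from mecp2core import simulate

        tables, _, truth = simulate.generate_multi_contrast(
            n_genes=200, n_contrasts=10, n_core_up=10, n_core_down=5,
            concordance=1.0, background_sig_rate=0.0, inverted_ids=(), seed=3,
        )
        cfg = ConsensusConfig(alpha=0.01, min_contrasts=4)
        _, res = core.run_core_pipeline(tables, cfg)
        assert res.core_up == truth.core_up and res.core_down == truth.core_down
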