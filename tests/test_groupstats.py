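import numpy as np
import pandas as pd
import pytest

from visconn.atlas import load_builtin_atlas
from visconn.distcorr import ConnectivityMatrix
from visconn.graphmetrics import LEProfile
from visconn.groupstats import (
    analyze_cohort,
    block_means,
    mixed_anova,
    pearson_acuity,
    storey_q,
    two_sample_t,
)

from .oracles import naive_split_plot_anova, naive_storey_q


def constant_matrix(atlas, c):
    v = np.full((19, 19), float(c))
    np.fill_diagonal(v, 0)
    return ConnectivityMatrix(v, atlas.labels)


class TestBlockMeans:
    def test_constant_matrix_all_blocks_equal(self, atlas):
        bs = block_means(constant_matrix(atlas, 0.4), atlas)
        assert all(np.isclose(v, 0.4) for v in bs.intra.values())
        assert all(np.isclose(v, 0.4) for v in bs.inter.values())

    def test_pvn_intra_is_the_single_v1_edge(self, atlas, rng):
        v = rng.uniform(0.1, 1.0, size=(19, 19))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        cm = ConnectivityMatrix(v, atlas.labels)
        bs = block_means(cm, atlas)
        i, j = atlas.labels.index("rV1"), atlas.labels.index("lV1")
        assert bs.intra["PVN"] == pytest.approx(v[i, j])

    def test_hand_computed_blocks(self, atlas, rng):
        v = rng.uniform(0.1, 1.0, size=(19, 19))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        cm = ConnectivityMatrix(v, atlas.labels)
        bs = block_means(cm, atlas)
        hvn = atlas.network_indices("HVN")
        hand = np.mean([v[a, b] for ai, a in enumerate(hvn)
                        for b in hvn[ai + 1:]])
        assert bs.intra["HVN"] == pytest.approx(hand)
        vsn = atlas.network_indices("VSN")
        hand_inter = np.mean([v[a, b] for a in hvn for b in vsn])
        assert bs.inter[("HVN", "VSN")] == pytest.approx(hand_inter)

    def test_label_mismatch_rejected(self, atlas):
        cm = constant_matrix(atlas, 0.2)
        cm.labels = list(reversed(cm.labels))
        with pytest.raises(ValueError, match="order"):
            block_means(cm, atlas)


class TestMixedAnova:
    def test_df_pattern_at_paper_design(self, rng):
        y = rng.standard_normal((36, 3))
        groups = ["patient"] * 18 + ["control"] * 18
        tab = mixed_anova(y, groups)
        assert tab.effects["group"][1] == (1, 34)
        assert tab.effects["condition"][1] == (2, 68)
        assert tab.effects["interaction"][1] == (2, 68)

    def test_location_invariance(self, rng):
        y = rng.standard_normal((12, 3))
        groups = ["a"] * 6 + ["b"] * 6
        t1 = mixed_anova(y, groups)
        t2 = mixed_anova(y + 17.3, groups)
        for eff in ("group", "condition", "interaction"):
            assert t1.effects[eff][0] == pytest.approx(t2.effects[eff][0],
                                                       abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_ss_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        n = int(rng.integers(3, 7))
        y = rng.standard_normal((2 * n, k))
        groups = ["a"] * n + ["b"] * n
        tab = mixed_anova(y, groups)
        oracle = naive_split_plot_anova(y, groups)
        for eff in ("group", "condition", "interaction"):
            assert tab.effects[eff][0] == pytest.approx(oracle[eff], abs=1e-10)
            assert tab.effects[eff][1] == oracle["df"][eff]

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.standard_normal((16, 3))
        groups = ["a"] * 8 + ["b"] * 8
        tab = mixed_anova(y, groups)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(16), 3),
            "group": np.repeat(groups, 3),
            "cond": list("xyz") * 16,
            "value": y.ravel(),
        })
        pg = pingouin.mixed_anova(df, dv="value", within="cond",
                                  between="group", subject="subject")
        pg = pg.set_index("Source")
        assert tab.effects["group"][0] == pytest.approx(pg.loc["group", "F"],
                                                        rel=1e-8)
        assert tab.effects["condition"][0] == pytest.approx(pg.loc["cond", "F"],
                                                            rel=1e-8)
        assert tab.effects["interaction"][0] == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-8)

    def test_interaction_equals_squared_difference_t(self, rng):
        """With 2 conditions and 2 groups, the interaction F equals the
        squared two-sample t on the condition differences."""
        y = rng.standard_normal((20, 2))
        groups = ["a"] * 10 + ["b"] * 10
        tab = mixed_anova(y, groups)
        diff = y[:, 0] - y[:, 1]
        t, _, _ = two_sample_t(diff[:10], diff[10:])
        assert tab.effects["interaction"][0] == pytest.approx(t**2, abs=1e-8)

    def test_unbalanced_design_rejected(self, rng):
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(rng.standard_normal((5, 3)), ["a", "a", "a", "b", "b"])

    def test_missing_values_rejected(self):
        y = np.ones((4, 2))
        y[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(y, ["a", "a", "b", "b"])


class TestTwoSampleT:
    def test_identical_groups_null(self):
        t, df, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # means 2 and 3, each sample variance 1, pooled SE = sqrt(2/3)
        t, df, p = two_sample_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1 / np.sqrt(2 / 3), abs=1e-12)
        assert df == 4

    def test_paper_design_df(self, rng):
        _, df, _ = two_sample_t(rng.standard_normal(18),
                                rng.standard_normal(18))
        assert df == 34

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestStoreyQ:
    def test_hand_oracle_example(self):
        q = storey_q([0.005, 0.1, 0.3, 0.9], lam=0.5)
        assert np.allclose(q, [0.01, 0.1, 0.2, 0.45], atol=1e-12)

    def test_all_ones(self):
        assert np.allclose(storey_q([1.0] * 5), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=int(rng.integers(3, 40)))
        q = storey_q(p)
        assert np.allclose(q, naive_storey_q(p), atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_pfdr_variant_at_least_as_large(self, rng):
        p = rng.uniform(0.001, 0.5, size=10)
        assert np.all(storey_q(p, pfdr=True) >= storey_q(p) - 1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            storey_q([])
        with pytest.raises(ValueError):
            storey_q([0.5, 1.2])
        with pytest.raises(ValueError):
            storey_q([0.5], lam=1.0)


class TestPearsonAcuity:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        out = pearson_acuity({"blk": 2 * x + 1}, x)
        assert out["blk"][0] == pytest.approx(1.0)

    def test_null_rejection_rate_near_alpha(self, rng):
        """|r| exceeds the critical value 0.468 (alpha = 0.05, df = 16) in
        about 5% of independent draws with n = 18."""
        crit = 0.468
        hits = sum(
            abs(np.corrcoef(rng.standard_normal(18),
                            rng.standard_normal(18))[0, 1]) > crit
            for _ in range(500)
        )
        rate = hits / 500
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / 500) <= rate \
            <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 500)

    def test_constant_acuity_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            pearson_acuity({"blk": rng.standard_normal(5)}, np.ones(5))


@pytest.fixture(scope="module")
def small_report():
    atlas = load_builtin_atlas()
    rng = np.random.default_rng(3)
    grid = np.array([0.2, 0.5, 0.8])
    matrices, profiles, rows = [], [], []
    for g, group in enumerate(["patient"] * 4 + ["control"] * 4):
        sid = f"s{g}"
        v = rng.uniform(0.1, 0.9, size=(19, 19))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        matrices.append(ConnectivityMatrix(v, atlas.labels, subject_id=sid))
        profiles.append(LEProfile(
            labels=atlas.labels, grid=grid,
            le=rng.uniform(0, 1, size=(19, 3)),
            ale=rng.uniform(0, 0.6, size=19), subject_id=sid))
        rows.append({"subject_id": sid, "group": group,
                     "acuity_amblyopic": rng.uniform(0.2, 1.0)})
    report = analyze_cohort(matrices, profiles, pd.DataFrame(rows), atlas)
    return report


class TestAnalyzeCohort:
    def test_family_sizes(self, small_report):
        assert len(small_report.intra_tests) == 3
        assert len(small_report.inter_tests) == 3
        assert len(small_report.node_tests) == 19

    def test_matrices_and_difference(self, small_report):
        assert small_report.mean_matrix["patient"].shape == (19, 19)
        assert np.allclose(
            small_report.diff_matrix,
            small_report.mean_matrix["patient"]
            - small_report.mean_matrix["control"])

    def test_anova_df_match_design(self, small_report):
        assert small_report.intra_anova.effects["group"][1] == (1, 6)
        assert small_report.intra_anova.effects["condition"][1] == (2, 12)
        assert small_report.ale_anova.effects["condition"][1] == (18, 108)

    def test_q_values_attached_and_monotone(self, small_report):
        for fam in (small_report.intra_tests, small_report.node_tests):
            ps = np.array([r.p for r in fam])
            qs = np.array([r.q for r in fam])
            order = np.argsort(ps)
            assert np.all(np.diff(qs[order]) >= -1e-12)

    def test_acuity_correlations_present(self, small_report):
        assert set(small_report.acuity_corr) == {
            "intra_HVN", "intra_PVN", "intra_VSN",
            "inter_HVN-PVN", "inter_HVN-VSN", "inter_PVN-VSN"}
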