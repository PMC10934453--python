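import numpy as np
import pytest
from scipy import stats as sps

from fluocube import anova_oneway, model_r2_rmse, summarize_maps, tukey_hsd


def perm_anova_p(groups, n_perm=100_000, seed=0):
    """Permutation oracle for the one-way ANOVA p-value."""
    pooled = np.concatenate(groups)
    ns = [len(g) for g in groups]
    obs = anova_oneway(groups).F
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(len(pooled))
    bounds = np.cumsum([0] + ns)
    perms = rng.permuted(np.tile(idx, (n_perm, 1)), axis=1)
    for row in perms:
        shuffled = pooled[row]
        gs = [shuffled[bounds[i] : bounds[i + 1]] for i in range(len(ns))]
        if anova_oneway(gs).F >= obs:
            count += 1
    return count / n_perm


class TestAnova:
    def test_hand_computed_three_groups(self):
        res = anova_oneway([np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])])
        assert res.F == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups_give_zero_f(self):
        res = anova_oneway([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert res.F == 0.0
        assert res.p == 1.0

    def test_zero_within_variance_sentinel(self):
        res = anova_oneway([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert res.F == float("inf")
        assert res.p == 0.0

    def test_p_matches_permutation_oracle(self):
        # continuous data with n=20 per group: the F-distribution p and the
        # permutation-null p agree within Monte-Carlo error (at n=3 per group
        # with tied integer values the permutation null is too discrete)
        rng = np.random.default_rng(5)
        groups = [rng.normal(loc, 1.0, 20) for loc in (0.0, 0.35, 0.55)]
        p_perm = perm_anova_p(groups, n_perm=20_000, seed=1)
        assert anova_oneway(groups).p == pytest.approx(p_perm, abs=0.01)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc, 1.0, size=12) for loc in (0.0, 0.3, 0.8)]
        ours = anova_oneway(groups)
        F, p = sps.f_oneway(*groups)
        assert ours.F == pytest.approx(F)
        assert ours.p == pytest.approx(p)

    def test_shift_and_scale_invariance_of_f(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc, 1.0, size=10) for loc in (0.0, 0.5)]
        base = anova_oneway(groups).F
        shifted = anova_oneway([g + 7.0 for g in groups]).F
        scaled = anova_oneway([g * 3.0 for g in groups]).F
        assert shifted == pytest.approx(base, rel=1e-10)
        assert scaled == pytest.approx(base, rel=1e-10)


class TestTukey:
    def test_identical_groups_share_a_letter(self):
        g = np.array([1.0, 2, 3, 4])
        res = tukey_hsd([g, g.copy()])
        assert not any(res.significant.values())
        assert res.letters[0] == res.letters[1]

    def test_widely_separated_groups_flagged(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(10.0, 1.0, 50)
        res = tukey_hsd([a, b], alpha=0.05)
        assert res.significant[(0, 1)]
        assert res.letters[0] != res.letters[1]

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(loc, 1.0, 15) for loc in (0.0, 0.5, 2.0)]
        ours = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for (i, j), p in ours.p_values.items():
            assert p == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_never_less_conservative_than_pairwise_t(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            groups = [rng.normal(rng.normal(0, 1), 1.0, rng.integers(5, 15)) for _ in range(4)]
            res = tukey_hsd(groups, alpha=0.05)
            for (i, j), sig in res.significant.items():
                if sig:
                    _, p_t = sps.ttest_ind(groups[i], groups[j])
                    assert p_t < 0.05  # Tukey flag implies the unadjusted t flag

    def test_agrees_with_max_t_permutation_oracle(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(0.0, 1.0, 8), rng.normal(0.1, 1.0, 8), rng.normal(3.0, 1.0, 8)]
        res = tukey_hsd(groups, alpha=0.05)

        pooled = np.concatenate(groups)
        bounds = np.cumsum([0] + [len(g) for g in groups])

        def max_abs_t(vals):
            gs = [vals[bounds[i] : bounds[i + 1]] for i in range(3)]
            df_w = len(pooled) - 3
            msw = sum(np.sum((g - g.mean()) ** 2) for g in gs) / df_w
            ts = []
            for i in range(3):
                for j in range(i + 1, 3):
                    se = np.sqrt(msw * (1 / len(gs[i]) + 1 / len(gs[j])))
                    ts.append(abs(gs[i].mean() - gs[j].mean()) / se)
            return np.array(ts)

        obs = max_abs_t(pooled)
        n_perm = 10_000
        null_max = np.empty(n_perm)
        for b in range(n_perm):
            null_max[b] = max_abs_t(rng.permutation(pooled)).max()
        crit = np.quantile(null_max, 0.95)
        oracle_flags = {(0, 1): obs[0] > crit, (0, 2): obs[1] > crit, (1, 2): obs[2] > crit}
        assert oracle_flags == res.significant


class TestModelR2Rmse:
    def test_perfect_prediction(self):
        y = np.array([0.0, 1, 0, 1])
        r2, rmse = model_r2_rmse(y, y)
        assert (r2, rmse) == (1.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([0.0, 1, 0, 1])
        r2, _ = model_r2_rmse(np.full(4, y.mean()), y)
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_six_element_vector(self):
        y = np.array([0.0, 0, 0, 1, 1, 1])
        pred = y + np.array([0.1, -0.1, 0.2, -0.2, 0.1, -0.1])
        ss_res = float(np.sum((y - pred) ** 2))  # 0.12
        ss_tot = 1.5
        r2, rmse = model_r2_rmse(pred, y)
        assert r2 == pytest.approx(1 - ss_res / ss_tot)
        assert rmse == pytest.approx(np.sqrt(ss_res / 6))

    def test_affine_predictions_match_squared_pearson(self):
        rng = np.random.default_rng(8)
        y = (rng.random(50) > 0.5).astype(float)
        # best-fit affine transform of an arbitrary score
        score = y + rng.normal(0, 0.5, 50)
        slope, icpt = np.polyfit(score, y, 1)
        pred = slope * score + icpt
        r2, _ = model_r2_rmse(pred, y)
        assert r2 == pytest.approx(np.corrcoef(pred, y)[0, 1] ** 2, abs=1e-10)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            model_r2_rmse(np.array([0.1, 0.2]), np.array([1.0, 1.0]))


class TestSummarizeMaps:
    def test_constant_maps(self):
        rng = np.random.default_rng(9)
        a = np.full((10, 10), 0.3) + rng.normal(0, 1e-9, (10, 10))
        b = np.full((10, 10), 0.7) + rng.normal(0, 1e-9, (10, 10))
        gs = summarize_maps({"lo": [a], "hi": [b]}, trim=(0.0, 100.0))
        assert gs.table["mean"].tolist() == pytest.approx([0.3, 0.7], abs=1e-6)
        assert gs.anova.p < 0.05

    def test_group_order_preserved(self):
        rng = np.random.default_rng(10)
        maps = {g: [rng.random((5, 5))] for g in ("Cg", "HL-1", "HL-2", "MHL-1", "MHL-2")}
        gs = summarize_maps(maps)
        assert gs.table["group"].tolist() == ["Cg", "HL-1", "HL-2", "MHL-1", "MHL-2"]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_maps({"only": [np.ones((3, 3))]})
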