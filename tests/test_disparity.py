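import numpy as np
import pandas as pd
import pytest
from scipy import stats

from airtrace.disparity import (
    CollinearityError,
    DegenerateInputError,
    add_interactions,
    games_howell,
    group_summary,
    hierarchical_stepwise_ols,
    one_way_anova,
    paired_t,
)

# coefficient pattern of the exposure regression used for recovery checks:
# intercept, urban, suburban, second_city, below_poverty, black, per-hour-away
GEN = dict(
    const=11.5, urban=8.3, suburban=3.4, second_city=2.6,
    below_poverty=1.7, black=1.2, hours_away=0.2,
)


def recovery_design(n=1000, seed=0, noise_sd=3.0):
    rng = np.random.default_rng(seed)
    zone = rng.choice(4, n, p=[0.25, 0.3, 0.25, 0.2])  # urban/sub/second/rural
    design = pd.DataFrame(
        {
            "urban": (zone == 0).astype(float),
            "suburban": (zone == 1).astype(float),
            "second_city": (zone == 2).astype(float),
            "below_poverty": rng.binomial(1, 0.15, n).astype(float),
            "black": rng.binomial(1, 0.2, n).astype(float),
            "hours_away": rng.uniform(0, 12, n),
        }
    )
    y = GEN["const"] + sum(
        GEN[c] * design[c] for c in design.columns
    ) + rng.normal(0, noise_sd, n)
    return design, y.to_numpy(), zone


class TestGroupSummary:
    def test_degenerate_constant_group(self):
        s = group_summary([5.0, 5.0, 5.0], ["a"] * 3)["a"]
        assert (s.mean, s.ci_lo, s.ci_hi) == (5.0, 5.0, 5.0)

    def test_four_point_group_t_interval(self):
        # mean 2.5, s = 1.2910, t_{0.975,3} = 3.1824 → CI (0.446, 4.554)
        s = group_summary([1.0, 2.0, 3.0, 4.0], ["g"] * 4)["g"]
        assert s.mean == pytest.approx(2.5)
        assert s.ci_lo == pytest.approx(0.446, abs=1e-3)
        assert s.ci_hi == pytest.approx(4.554, abs=1e-3)

    def test_median_of_1_to_100_interpolates(self):
        s = group_summary(np.arange(1, 101, dtype=float), ["g"] * 100)["g"]
        assert s.percentiles[50] == pytest.approx(50.5)
        assert s.minimum == 1.0 and s.maximum == 100.0

    def test_percentiles_ordered(self):
        rng = np.random.default_rng(0)
        s = group_summary(rng.normal(size=200), ["g"] * 200)["g"]
        p = s.percentiles
        assert s.minimum <= p[5] <= p[25] <= p[50] <= p[75] <= p[95] <= s.maximum


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        f, df1, df2, p = one_way_anova([a, b])
        t, _ = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert (df1, df2) == (1, 53)

    def test_identical_means_give_small_f(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10, 2, 200)
        f, *_, p = one_way_anova([base, base.copy(), base.copy()])
        assert f == pytest.approx(0.0, abs=1e-12) and p > 0.99

    def test_three_sd_shift_is_highly_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 50)
        b = rng.normal(3, 1, 50)
        *_, p = one_way_anova([a, b])
        assert p < 0.001

    def test_degenerate_all_identical(self):
        with pytest.raises(DegenerateInputError):
            one_way_anova([np.ones(5), np.ones(5)])


class TestGamesHowell:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(4)
        g = rng.normal(0, 1, 40)
        res = games_howell({"a": g, "b": g.copy()})
        assert res[0].p_value == pytest.approx(1.0, abs=1e-9)
        assert not res[0].significant

    def test_two_groups_reduce_to_welch_t(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.7, 2.5, 55)
        res = games_howell({"a": a, "b": b})[0]
        t, p_welch = stats.ttest_ind(a, b, equal_var=False)
        assert res.p_value == pytest.approx(p_welch, abs=1e-6)
        assert res.statistic == pytest.approx(abs(t) * np.sqrt(2), rel=1e-9)

    def test_matches_independent_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        data = pd.DataFrame(
            {
                "y": np.concatenate(
                    [
                        rng.normal(0, 1, 20),
                        rng.normal(0.8, 2, 35),
                        rng.normal(1.5, 0.5, 28),
                    ]
                ),
                "g": ["a"] * 20 + ["b"] * 35 + ["c"] * 28,
            }
        )
        ours = games_howell(
            {g: data.loc[data.g == g, "y"].to_numpy() for g in ("a", "b", "c")}
        )
        ref = pg.pairwise_gameshowell(data=data, dv="y", between="g")
        for cmp_ in ours:
            row = ref[(ref.A == cmp_.group_i) & (ref.B == cmp_.group_j)]
            assert cmp_.p_value == pytest.approx(float(row.pval.iloc[0]), abs=1e-4)
            assert cmp_.df == pytest.approx(float(row.df.iloc[0]), rel=1e-6)

    def test_invariance_to_relabeling_and_shift(self):
        rng = np.random.default_rng(7)
        groups = {f"g{i}": rng.normal(i, 1 + i, 25) for i in range(3)}
        base = {
            frozenset((c.group_i, c.group_j)): c.p_value
            for c in games_howell(groups)
        }
        renamed = {f"z{i}": groups[f"g{i}"] + 100.0 for i in range(3)}
        for c in games_howell(renamed):
            key = frozenset((c.group_i.replace("z", "g"), c.group_j.replace("z", "g")))
            assert c.p_value == pytest.approx(base[key], rel=1e-12)

    def test_approaches_tukey_for_homoscedastic_equal_n(self):
        # equal variances and sizes: the Welch pair df (≈2(n−1)) approaches
        # the pooled df (3n−3) effect only asymptotically, so compare at n=500
        rng = np.random.default_rng(8)
        groups = {f"g{i}": rng.normal(i * 0.09, 1.0, 500) for i in range(3)}
        ours = games_howell(groups)
        ref = stats.tukey_hsd(*groups.values())
        pairs = {("g0", "g1"): (0, 1), ("g0", "g2"): (0, 2), ("g1", "g2"): (1, 2)}
        for c in ours:
            i, j = pairs[(c.group_i, c.group_j)]
            assert c.p_value == pytest.approx(ref.pvalue[i, j], abs=0.01)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            games_howell({"a": np.ones(5), "b": np.array([1.0, 2.0, 3.0])})


class TestPairedT:
    def test_equal_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = paired_t(a, a)
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        a = np.arange(10, dtype=float)
        t, df, p = paired_t(a + 1.0, a)
        assert np.isinf(t) and t > 0 and p == 0.0 and df == 9

    def test_matches_scipy_on_regular_data(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 50)
        b = a + rng.normal(0.3, 1, 50)
        t, df, p = paired_t(a, b)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)

    def test_power_at_moderate_effect(self):
        # d ~ N(0.5, 1), n = 200: significant in at least 95 of 100 replicates
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(100):
            b = rng.normal(0, 1, 200)
            a = b + rng.normal(0.5, 1, 200)
            *_, p = paired_t(a, b)
            hits += p < 0.05
        assert hits >= 95


class TestStepwise:
    def test_estimator_is_unbiased_with_nominal_ci_coverage(self):
        # a single draw of the 6-coefficient recovery has only ~0.95⁶ ≈ 74 %
        # joint probability of every marginal CI covering its target, so
        # assert the distributional properties over 20 replicates instead:
        # near-nominal per-coefficient coverage and replicate-mean estimates
        # close to the generating values
        reps = 20
        coverage = {name: 0 for name in GEN if name != "const"}
        sums = {name: 0.0 for name in coverage}
        kept = {name: 0 for name in coverage}
        blocks = [["black"], ["below_poverty"],
                  ["urban", "suburban", "second_city"], ["hours_away"]]
        for rep in range(reps):
            design, y, zone = recovery_design(n=1000, seed=rep, noise_sd=3.0)
            res = hierarchical_stepwise_ols(design, y, blocks)
            for name in coverage:
                if name not in res.retained:
                    continue  # counts as a miss
                est = res.params[name]
                se = abs(est / res.tvalues[name])
                sums[name] += est
                kept[name] += 1
                coverage[name] += abs(est - GEN[name]) <= 1.96 * se
        for name in coverage:
            assert coverage[name] >= 0.75 * reps, name
            assert sums[name] / kept[name] == pytest.approx(GEN[name], abs=0.35), name

    def test_group_mean_ordering_follows_urbanicity_gradient(self):
        _, y, zone = recovery_design(n=1000, seed=0, noise_sd=3.0)
        means = [y[zone == k].mean() for k in range(4)]
        assert means[0] > means[1] > means[2] > means[3]

    def test_zero_noise_interpolates_exactly(self):
        design, y, _ = recovery_design(n=400, seed=13, noise_sd=0.0)
        res = hierarchical_stepwise_ols(design, y, [list(design.columns)])
        for name, true_val in GEN.items():
            assert res.params[name] == pytest.approx(true_val, abs=1e-8)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_block_retention_rate_near_alpha(self):
        # a noise predictor entered in its own block should be retained with
        # probability ≈ alpha = 0.05
        retained = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            design = pd.DataFrame(
                {"x": rng.normal(size=150), "noise": rng.normal(size=150)}
            )
            y = 2.0 + 1.5 * design["x"].to_numpy() + rng.normal(0, 1, 150)
            res = hierarchical_stepwise_ols(design, y, [["x"], ["noise"]])
            retained += "noise" in res.retained
        assert 0.005 <= retained / n_rep <= 0.12

    def test_earlier_blocks_are_never_re_dropped(self):
        # x1 significant alone, made redundant by block 2; it must stay
        rng = np.random.default_rng(14)
        x1 = rng.normal(size=300)
        x2 = x1 + rng.normal(0, 0.1, 300)
        y = x2 + rng.normal(0, 0.5, 300)
        design = pd.DataFrame({"x1": x1, "x2": x2})
        res = hierarchical_stepwise_ols(design, y, [["x1"], ["x2"]])
        assert "x1" in res.retained

    def test_deterministic_given_design_and_blocks(self):
        design, y, _ = recovery_design(n=300, seed=15)
        blocks = [["black", "below_poverty"], ["urban", "suburban", "second_city"],
                  ["hours_away"]]
        r1 = hierarchical_stepwise_ols(design, y, blocks)
        r2 = hierarchical_stepwise_ols(design, y, blocks)
        assert r1.retained == r2.retained
        assert np.array_equal(r1.params.to_numpy(), r2.params.to_numpy())

    def test_collinear_design_names_offenders(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=100)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(CollinearityError, match="[ab]"):
            hierarchical_stepwise_ols(design, x, [["a", "b"]])


class TestInteractions:
    def test_binary_product(self):
        d = pd.DataFrame({"urban": [1.0, 1.0, 0.0], "black": [1.0, 0.0, 1.0]})
        out = add_interactions(d, [("urban", "black")])
        assert list(out["urban×black"]) == [1.0, 0.0, 0.0]

    def test_unknown_column_rejected(self):
        with pytest.raises(KeyError):
            add_interactions(pd.DataFrame({"a": [1.0]}), [("a", "zzz")])

    def test_self_interaction_of_binary_flagged_collinear(self):
        rng = np.random.default_rng(17)
        d = pd.DataFrame({"a": rng.binomial(1, 0.5, 50).astype(float)})
        out = add_interactions(d, [("a", "a")])
        assert (out["a×a"] == out["a"]).all()
        with pytest.raises(CollinearityError):
            hierarchical_stepwise_ols(out, rng.normal(size=50), [["a", "a×a"]])

    def test_null_interactions_leave_base_coefficients_within_ci(self):
        design, y, _ = recovery_design(n=1000, seed=18, noise_sd=3.0)
        with_int = add_interactions(
            design, [("urban", "black"), ("suburban", "below_poverty")]
        )
        res = hierarchical_stepwise_ols(
            with_int, y, [list(design.columns)
                          + ["urban×black", "suburban×below_poverty"]]
        )
        for name in ("urban", "suburban", "black"):
            est = res.params[name]
            se = abs(est / res.tvalues[name])
            assert abs(est - GEN[name]) <= 1.96 * se + 1e-9, name
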