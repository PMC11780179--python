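import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gatedlung import (
    brown_forsythe,
    compare_groups,
    describe_groups,
    dunnett_t3,
    one_way_anova,
    permutation_oracle,
    simulate_measured_cohort,
    tukey_hsd,
    welch_anova,
)
from .oracles import mc_studentized_range_sf


@pytest.fixture(scope="module")
def gaussian_fixture():
    rng = np.random.default_rng(101)
    return {
        "a": rng.normal(0.0, 1.0, 6),
        "b": rng.normal(0.8, 1.2, 8),
        "c": rng.normal(0.3, 0.9, 7),
    }


class TestOneWayAnova:
    def test_hand_computed_sums_of_squares(self):
        """Groups {0,2} and {1,3}: SSB=1, SSW=4 => F = 1/(4/2) = 0.5."""
        res = one_way_anova({"a": [0.0, 2.0], "b": [1.0, 3.0]})
        assert res.statistic == pytest.approx(0.5)
        assert res.df == (1, 2)

    def test_equals_squared_pooled_t_for_two_groups(self, gaussian_fixture):
        a, b = gaussian_fixture["a"], gaussian_fixture["b"]
        res = one_way_anova({"a": a, "b": b})
        t = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_identical_groups_give_zero_f(self):
        res = one_way_anova({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_within_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="zero within-group"):
            res = one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.p_value == 0.0

    def test_matches_scipy_f_oneway(self, gaussian_fixture):
        res = one_way_anova(gaussian_fixture)
        ref = sps.f_oneway(*gaussian_fixture.values())
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})

    def test_agrees_with_permutation_oracle(self, gaussian_fixture):
        p = one_way_anova(gaussian_fixture).p_value
        p_perm = permutation_oracle(gaussian_fixture, n_perm=10_000, seed=7)
        assert abs(p - p_perm) < 0.02

    def test_type_one_error_calibration(self):
        """Exactness under the null: rejection rate ~5% for 3 equal
        Gaussian groups at n=6."""
        rng = np.random.default_rng(11)
        n_rep = 4000
        rej = 0
        for _ in range(n_rep):
            g = {k: rng.normal(0.0, 1.0, 6) for k in "abc"}
            if one_way_anova(g).p_value < 0.05:
                rej += 1
        assert 0.04 <= rej / n_rep <= 0.06


class TestTukey:
    def test_equal_means_give_p_one(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 3.0], "c": [3.0, 2.0, 1.0]}
        tab = tukey_hsd(g)
        assert (tab["p_adj"] > 0.999).all()

    def test_two_groups_reduce_to_pooled_t(self, gaussian_fixture):
        """k=2: q = sqrt(2)|t| and the adjusted p is the t-test p."""
        a, b = gaussian_fixture["a"], gaussian_fixture["b"]
        tab = tukey_hsd({"a": a, "b": b})
        t = sps.ttest_ind(a, b)
        assert tab["q"].iloc[0] == pytest.approx(np.sqrt(2) * abs(t.statistic), rel=1e-9)
        assert tab["p_adj"].iloc[0] == pytest.approx(t.pvalue, rel=1e-6)

    def test_matches_scipy_tukey(self, gaussian_fixture):
        tab = tukey_hsd(gaussian_fixture)
        ref = sps.tukey_hsd(*gaussian_fixture.values())
        expected = [ref.pvalue[0, 1], ref.pvalue[0, 2], ref.pvalue[1, 2]]
        np.testing.assert_allclose(tab["p_adj"], expected, atol=1e-9)

    def test_matches_monte_carlo_studentized_range(self, gaussian_fixture):
        """Adjusted p within 0.005 of a 1e6-draw MC oracle."""
        tab = tukey_hsd(gaussian_fixture)
        k = 3
        df = sum(len(v) for v in gaussian_fixture.values()) - k
        for _, row in tab.iterrows():
            p_mc = mc_studentized_range_sf(row["q"], k, df, 1_000_000, seed=3)
            assert abs(row["p_adj"] - p_mc) < 0.005

    def test_adjusted_p_never_below_unadjusted_t(self, gaussian_fixture):
        tab = tukey_hsd(gaussian_fixture)
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        for (ga, gb), (_, row) in zip(pairs, tab.iterrows()):
            p_t = sps.ttest_ind(gaussian_fixture[ga], gaussian_fixture[gb]).pvalue
            assert row["p_adj"] >= p_t - 1e-9


class TestWelchBrownForsythe:
    def test_welch_equals_classical_for_equal_variance_two_groups(self):
        """Two balanced groups with identical sample variances: the Welch
        statistic coincides with the classical F."""
        a = np.array([0.0, 1.0, 2.0, 3.0])
        b = a + 10.0  # same sample variance by construction
        w = welch_anova({"a": a, "b": b})
        f = one_way_anova({"a": a, "b": b})
        assert w.statistic == pytest.approx(f.statistic, abs=1e-6)

    def test_welch_equals_squared_welch_t(self, gaussian_fixture):
        a, b = gaussian_fixture["a"], gaussian_fixture["b"]
        w = welch_anova({"a": a, "b": b})
        t = sps.ttest_ind(a, b, equal_var=False)
        assert w.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert w.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_welch_matches_pingouin(self, gaussian_fixture):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            [(k, v) for k, vals in gaussian_fixture.items() for v in vals],
            columns=["g", "y"],
        )
        ref = pg.welch_anova(dv="y", between="g", data=df)
        w = welch_anova(gaussian_fixture)
        assert w.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert w.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)
        assert w.df[1] == pytest.approx(float(ref["ddof2"][0]), rel=1e-9)

    def test_equal_means_near_zero_statistic(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 3.0], "c": [3.0, 1.0, 2.0]}
        assert welch_anova(g).statistic == pytest.approx(0.0, abs=1e-12)
        assert brown_forsythe(g).statistic == pytest.approx(0.0, abs=1e-12)
        assert welch_anova(g).p_value > 0.99

    def test_zero_variance_rejected(self):
        g = {"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}
        with pytest.raises(ValueError, match="undefined"):
            welch_anova(g)
        with pytest.raises(ValueError, match="undefined"):
            brown_forsythe(g)

    def test_brown_forsythe_reduces_to_f_for_balanced_equal_variance(self):
        """Balanced design, equal sample variances: F* = F exactly."""
        a = np.array([0.0, 1.0, 2.0, 3.0])
        g = {"a": a, "b": a + 5.0, "c": a - 2.0}
        bf = brown_forsythe(g)
        f = one_way_anova(g)
        assert bf.statistic == pytest.approx(f.statistic, rel=1e-12)


class TestDunnettT3:
    def test_two_groups_match_welch_t(self, gaussian_fixture):
        a, b = gaussian_fixture["a"], gaussian_fixture["b"]
        tab = dunnett_t3({"a": a, "b": b}, n_draws=1_000_000)
        t = sps.ttest_ind(a, b, equal_var=False)
        assert tab["p_adj"].iloc[0] == pytest.approx(t.pvalue, abs=0.005)

    def test_separated_means_all_significant(self):
        g = {"a": [0.0, 0.01, -0.01], "b": [10.0, 10.01, 9.99],
             "c": [20.0, 20.01, 19.99]}
        tab = dunnett_t3(g, n_draws=200_000)
        assert (tab["p_adj"] < 1e-3).all()
        assert tab["significant"].all()

    def test_familywise_error_under_null(self):
        """All groups drawn from one distribution: FWER near alpha."""
        rng = np.random.default_rng(202)
        n_rep = 1000
        rej = 0
        for _ in range(n_rep):
            g = {k: rng.normal(0.0, 1.0, 10) for k in "abc"}
            tab = dunnett_t3(g, n_draws=20_000, seed=int(rng.integers(2**31)))
            if tab["significant"].any():
                rej += 1
        assert 0.03 <= rej / n_rep <= 0.07

    def test_deterministic_given_seed(self, gaussian_fixture):
        t1 = dunnett_t3(gaussian_fixture, n_draws=50_000, seed=9)
        t2 = dunnett_t3(gaussian_fixture, n_draws=50_000, seed=9)
        pd.testing.assert_frame_equal(t1, t2)


class TestPermutationOracle:
    def test_label_invariant_statistic_gives_p_one(self, gaussian_fixture):
        p = permutation_oracle(
            gaussian_fixture, statistic=lambda parts: 1.0, n_perm=2000, seed=0
        )
        assert p == pytest.approx(1.0, abs=0.01)

    def test_deterministic(self, gaussian_fixture):
        p1 = permutation_oracle(gaussian_fixture, n_perm=2000, seed=5)
        p2 = permutation_oracle(gaussian_fixture, n_perm=2000, seed=5)
        assert p1 == p2

    def test_too_few_permutations_rejected(self, gaussian_fixture):
        with pytest.raises(ValueError, match="1000"):
            permutation_oracle(gaussian_fixture, n_perm=10)


class TestDescribeAndWiring:
    def test_describe_groups(self):
        out = describe_groups({"a": [1.0, 2.0, 3.0]}).iloc[0]
        assert out["n"] == 3
        assert out["mean"] == 2.0
        assert out["sd"] == pytest.approx(1.0)
        assert out["ci95_lo"] < 2.0 < out["ci95_hi"]

    def test_compare_groups_long_format(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            dict(
                group=np.repeat(["a", "b", "c"], 6),
                frc_ml=np.concatenate(
                    [rng.normal(m, 0.05, 6) for m in (0.4, 0.4, 0.2)]
                ),
            )
        )
        res = compare_groups(df, "frc_ml", method="anova_tukey")
        assert res.p_value < 0.05
        sig = res.pairwise[res.pairwise["significant"]]
        assert any("c" in p for p in sig["pair"])
        res2 = compare_groups(df, "frc_ml", method="welch_t3")
        assert res2.method == "Welch ANOVA"
        assert "brown_forsythe" in res2.pairwise.attrs


class TestEffectAndNullRecovery:
    def test_power_for_halved_frc(self):
        """ANOVA+Tukey flags a 50% FRC reduction at n=6 in >=80% of
        replicates under realistic biological + measurement noise."""
        hits = 0
        n_rep = 100
        for r in range(n_rep):
            g = simulate_measured_cohort(
                {"control": 0.04, "sham": 0.04, "treated": 0.02}, seed=30_000 + r
            )
            res = one_way_anova(g)
            tab = tukey_hsd(g)
            pair = tab[tab["pair"] == "control vs treated"]
            if res.p_value < 0.05 and bool(pair["significant"].iloc[0]):
                hits += 1
        assert hits / n_rep >= 0.8
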