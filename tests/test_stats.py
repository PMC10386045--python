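import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from aacidcest.stats import (
    paired_t,
    rm_anova_gg,
    shapiro_wilk,
    significance_stars,
    tukey_posthoc,
)

# Frozen oracle values from R (car::Anova type-III repeated measures and
# shapiro.test) on the deterministic fixtures below.
R_RM_ORACLE = {
    "side": {"F": 17.19893, "eps": 1.0, "p": 0.0089347},
    "time": {"F": 15.74492, "eps": 0.746511841727, "p": 0.000444730935082},
    "side*time": {"F": 1.65759, "eps": 0.794389007522, "p": 0.231146515253949},
}
SW_SAMPLE = [
    1.354313, 1.305406, 1.32313, 1.350503, 1.183428, 1.274426,
    1.26237, 1.24889, 1.277989, 1.419595, 1.230734, 1.377462,
]
R_SW = {"W": 0.9886259516, "p": 0.9993927451}


class TestShapiroWilk:
    def test_matches_r_oracle(self):
        res = shapiro_wilk(SW_SAMPLE)
        assert res.statistic == pytest.approx(R_SW["W"], abs=1e-6)
        assert res.p == pytest.approx(R_SW["p"], abs=1e-6)

    def test_normal_samples_rarely_flagged(self):
        rng = np.random.default_rng(101)
        ws = [shapiro_wilk(rng.normal(1.3, 0.1, 50)).statistic for _ in range(200)]
        assert np.mean(np.asarray(ws) > 0.95) >= 0.95

    def test_bimodal_sample_strongly_rejected(self):
        x = np.concatenate([np.zeros(25), np.full(25, 10.0)]) + np.linspace(0, 1e-6, 50)
        assert shapiro_wilk(x).p < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.full(10, 1.3))

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestRmAnovaGG:
    def test_matches_r_car_oracle(self, rm_table):
        res = rm_anova_gg(rm_table, within=("side", "time"))
        for effect, ref in R_RM_ORACLE.items():
            r = res[effect]
            assert r.statistic == pytest.approx(ref["F"], abs=5e-5)
            assert r.epsilon == pytest.approx(ref["eps"], abs=1e-6)
            assert r.p == pytest.approx(ref["p"], abs=1e-6)

    def test_two_level_factor_has_epsilon_one(self, rm_table):
        res = rm_anova_gg(rm_table, within=("side", "time"))
        assert res["side"].epsilon == 1.0

    def test_matches_pingouin_on_random_tables(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        for _ in range(100):
            n, q = rng.integers(4, 8), rng.integers(3, 6)
            rows = [
                (s, a, b, rng.normal(1.0 + 0.1 * a, 0.1))
                for s in range(n)
                for a in range(2)
                for b in range(q)
            ]
            df = pd.DataFrame(rows, columns=["subject", "side", "time", "value"])
            ours = rm_anova_gg(df, within=("side", "time"))
            ref = pg.rm_anova(
                data=df, dv="value", within=["side", "time"], subject="subject", correction=True
            ).set_index("Source")
            for effect, key in [("side", "side"), ("time", "time"), ("side*time", "side * time")]:
                assert ours[effect].statistic == pytest.approx(ref.loc[key, "F"], abs=1e-6)
                assert ours[effect].p == pytest.approx(ref.loc[key, "p_GG_corr"], abs=1e-6)

    def test_missing_cells_rejected(self, rm_table):
        with pytest.raises(ValueError):
            rm_anova_gg(rm_table.iloc[:-1], within=("side", "time"))

    def test_single_subject_rejected(self, rm_table):
        with pytest.raises(ValueError):
            rm_anova_gg(rm_table[rm_table.subject == 0], within=("side", "time"))

    def test_null_rejection_rate_near_alpha(self):
        # abridged null calibration; the full 500-replicate version runs in
        # the acceptance suite
        rng = np.random.default_rng(55)
        rejections = 0
        n_rep = 150
        for _ in range(n_rep):
            rows = [
                (s, a, b, rng.normal(1.3, 0.05))
                for s in range(10)
                for a in range(2)
                for b in range(3)
            ]
            df = pd.DataFrame(rows, columns=["subject", "side", "time", "value"])
            if rm_anova_gg(df, within=("side", "time"))["time"].p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_rep <= 0.09


class TestTukey:
    def test_two_levels_reduce_to_paired_comparison(self):
        rng = np.random.default_rng(21)
        rows = [(s, b, rng.normal(1.0 + 0.05 * b, 0.05)) for s in range(8) for b in range(2)]
        df = pd.DataFrame(rows, columns=["subject", "time", "value"])
        (res,) = tukey_posthoc(df, factor="time")
        wide = df.pivot(index="subject", columns="time", values="value")
        t_res = paired_t(wide[1], wide[0])
        assert res.statistic == pytest.approx(np.sqrt(2) * abs(t_res.statistic), rel=1e-9)
        assert res.p_adjusted == pytest.approx(
            float(sps.studentized_range.sf(np.sqrt(2) * abs(t_res.statistic), 2, 7)), abs=1e-12
        )
        # with k = 2 the range test and the paired t test agree exactly
        assert res.p_adjusted == pytest.approx(t_res.p, abs=1e-9)

    def test_identical_level_means_not_significant(self):
        rows = [(s, b, 1.0 + 0.01 * s) for s in range(6) for b in range(4)]
        df = pd.DataFrame(rows, columns=["subject", "time", "value"])
        for res in tukey_posthoc(df, factor="time"):
            assert res.p_adjusted == pytest.approx(1.0)

    def test_single_level_rejected(self):
        df = pd.DataFrame({"subject": [0, 1], "time": [0, 0], "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            tukey_posthoc(df, factor="time")


class TestPairedT:
    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_highly_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(10, 1, 8)
        b = a + 1.0 + rng.normal(0, 1e-3, 8)
        res = paired_t(b, a)
        assert res.statistic > 100 and res.p < 0.001

    def test_symmetric_differences_give_t_zero(self):
        res = paired_t([1.0, -1.0], [0.0, 0.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(12.4, 2, 10), rng.normal(103.5, 27, 10)
        ours = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [(0.03, "*"), (0.0005, "***"), (0.2, "ns"), (0.009, "**"), (5e-5, "****"), (0.05, "ns")],
    )
    def test_thresholds(self, p, label):
        assert significance_stars(p) == label

    @settings(derandomize=True, max_examples=200)
    @given(p1=st.floats(0, 1), p2=st.floats(0, 1))
    def test_monotone_non_increasing(self, p1, p2):
        order = ["****", "***", "**", "*", "ns"]
        lo, hi = sorted([p1, p2])
        assert order.index(significance_stars(lo)) <= order.index(significance_stars(hi))
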