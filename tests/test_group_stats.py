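"""Within-subject statistics: brute-force oracles, reference cross-checks,
null calibration, and the published-design degrees of freedom."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vreeg import (
    PairedDesign,
    bonferroni_posthoc,
    percent_change,
    rm_anova,
    wilks_one_sample,
)


def brute_force_rm_anova(y):
    """Loop-based sums-of-squares decomposition, independent of the module."""
    n, c = y.shape
    grand = y.mean()
    ss_cond = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(c))
    ss_subj = sum(c * (y[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(c))
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = c - 1, (c - 1) * (n - 1)
    f = (ss_cond / df1) / (ss_err / df2)
    eta = ss_cond / (ss_cond + ss_err)
    return f, df1, df2, eta


class TestRMAnova:
    def test_identical_conditions_give_zero_effect(self):
        col = np.random.default_rng(0).normal(size=6)
        design = PairedDesign(values=np.column_stack([col, col, col]))
        res = rm_anova(design)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_published_design_degrees_of_freedom(self):
        y = np.random.default_rng(1).normal(size=(15, 3))
        res = rm_anova(PairedDesign(values=y))
        assert (res.df1, res.df2) == (2.0, 28.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.normal(size=(5, 3)) + rng.normal(scale=2, size=(5, 1))
            res = rm_anova(PairedDesign(values=y))
            f, df1, df2, eta = brute_force_rm_anova(y)
            assert res.statistic == pytest.approx(f, abs=1e-10)
            assert res.effect_size == pytest.approx(eta, abs=1e-10)
            assert res.p == pytest.approx(stats.f.sf(f, df1, df2), abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        y = rng.normal(size=(8, 3))
        res = rm_anova(PairedDesign(values=y))
        df = pd.DataFrame(
            {"s": np.repeat(range(8), 3), "c": list("ABC") * 8, "v": y.ravel()}
        )
        ref = pg.rm_anova(data=df, dv="v", within="c", subject="s", effsize="np2")
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)
        assert res.effect_size == pytest.approx(float(ref["np2"][0]), rel=1e-9)

    def test_invariant_to_per_subject_constants(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(10, 3))
        shifted = y + rng.normal(scale=50, size=(10, 1))
        assert rm_anova(PairedDesign(values=shifted)).statistic == pytest.approx(
            rm_anova(PairedDesign(values=y)).statistic, rel=1e-8
        )

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            rm_anova(PairedDesign(values=rng.normal(size=(15, 3)))).p < 0.05
            for _ in range(500)
        )
        # binomial 95% CI around 0.05 at 500 replicates: [0.031, 0.069]
        assert 0.031 <= rejections / 500 <= 0.069

    def test_design_validation(self):
        with pytest.raises(ValueError):
            PairedDesign(values=np.zeros((2, 3)))  # too few subjects
        bad = np.zeros((5, 3))
        bad[1, 2] = np.nan
        with pytest.raises(ValueError):
            PairedDesign(values=bad)


class TestWilksOneSample:
    def test_zero_differences_are_null_identity(self):
        res = wilks_one_sample(np.zeros((10, 3)))
        assert res.statistic == 1.0  # Wilks' lambda
        assert res.effect_size == 0.0
        assert res.p == 1.0

    def test_published_design_df_6_9(self):
        d = np.random.default_rng(6).normal(size=(15, 6))
        res = wilks_one_sample(d)
        assert (res.df1, res.df2) == (6.0, 9.0)

    def test_single_variable_reduces_to_paired_t_squared(self):
        d = np.random.default_rng(7).normal(0.3, 1, size=(12, 1))
        res = wilks_one_sample(d)
        t, p = stats.ttest_1samp(d[:, 0], 0.0)
        f = (res.df2 / res.df1) * (1 - res.statistic) / res.statistic
        assert f == pytest.approx(t**2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_matches_pingouin_hotelling(self):
        pg = pytest.importorskip("pingouin")
        d = np.random.default_rng(8).normal(0.5, 1, size=(15, 6))
        res = wilks_one_sample(d)
        ref = pg.multivariate_ttest(d)
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-9)
        t2 = float(ref["T2"].iloc[0])
        assert res.statistic == pytest.approx(1 / (1 + t2 / 14), rel=1e-9)

    def test_p_values_uniform_under_null(self):
        rng = np.random.default_rng(9)
        pvals = [wilks_one_sample(rng.normal(size=(15, 4))).p for _ in range(500)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_singularity_and_dimension_errors(self):
        with pytest.raises(ValueError, match="subjects"):
            wilks_one_sample(np.random.default_rng(0).normal(size=(5, 6)))
        d = np.random.default_rng(1).normal(size=(10, 2))
        d[:, 1] = 2 * d[:, 0] + 1e-3  # nearly collinear is fine; exact is not
        d_exact = np.column_stack([d[:, 0], 2 * d[:, 0]])
        with pytest.raises(ValueError, match="singular"):
            wilks_one_sample(d_exact)


class TestBonferroni:
    def test_identical_conditions_all_null(self):
        col = np.random.default_rng(10).normal(size=8)
        results = bonferroni_posthoc(PairedDesign(values=np.column_stack([col] * 3)))
        assert len(results) == 3
        assert all(r.p_adjusted == 1.0 and not r.significant for r in results)

    def test_multiplication_rule(self):
        # raw p of 0.02 adjusts to 0.06 over a family of three
        rng = np.random.default_rng(11)
        for _ in range(50):
            y = rng.normal(size=(9, 3)) + [0.0, 0.6, 0.1]
            for r in bonferroni_posthoc(PairedDesign(values=y)):
                assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw), abs=1e-15)
                assert r.significant == (r.p_adjusted < 0.05)

    def test_t_matches_hand_rolled_oracle(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(6, 3))
        results = bonferroni_posthoc(PairedDesign(values=y))
        for r, (i, j) in zip(results, [(0, 1), (0, 2), (1, 2)]):
            diff = y[:, i] - y[:, j]
            t_oracle = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
            assert r.t == pytest.approx(t_oracle, abs=1e-10)
            assert r.df == 5


class TestPercentChange:
    @pytest.mark.parametrize(
        "baseline,task,expected",
        [(1.58, 1.66, 5.06), (1.56, 1.67, 7.05), (2.34, 2.34, 0.00)],
    )
    def test_reference_values(self, baseline, task, expected):
        assert round(percent_change(baseline, task), 2) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)
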