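import math

import numpy as np
import pandas as pd
import pytest

from antnav import stats
from antnav.types import DesignError, InsufficientDataError


def welch_oracle(x, y):
    """Textbook Welch t with Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    t = (x.mean() - y.mean()) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return t, df


class TestWelch:
    def test_identical_samples(self):
        r = stats.welch_t_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x = [1.0, 2, 3, 4, 5]
        y = [2.0, 3, 4, 5, 6]
        r = stats.welch_t_test(x, y)
        t, df = welch_oracle(x, y)
        assert r.t == pytest.approx(t, abs=1e-10)
        assert r.df == pytest.approx(df, abs=1e-10)
        assert np.sign(r.t) == np.sign(r.mean_1 - r.mean_2)

    def test_df_at_most_28_for_two_groups_of_15(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        r = stats.welch_t_test(x, y)
        assert r.df <= 28.0 + 1e-12

    def test_welch_equals_pooled_with_equal_variances_and_ns(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = x + 1.0  # same variance, same n
        w = stats.welch_t_test(x, y)
        p = stats.welch_t_test(x, y, pooled=True)
        assert w.t == pytest.approx(p.t, abs=1e-12)
        assert w.df == pytest.approx(p.df, abs=1e-12)

    def test_degenerate_zero_variance_flagged(self):
        r = stats.welch_t_test([2.0, 2, 2], [2.0, 2, 2])
        assert r.t == 0.0 and r.p == 1.0 and "degenerate" in r.flags

    def test_tiny_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.welch_t_test([1.0], [1.0, 2.0])


def rm_anova_oracle(data):
    """Independent two-way (subject x condition) sums-of-squares decomposition."""
    data = np.asarray(data, float)
    n, k = data.shape
    grand = data.mean()
    ss_total = ((data - grand) ** 2).sum()
    ss_cond = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_err = ss_total - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestRmAnova:
    def test_identical_conditions_give_zero_f(self):
        data = np.tile(np.arange(1.0, 6.0)[:, None], (1, 4))
        res = stats.rm_anova(data)
        assert res.F == pytest.approx(0.0)

    def test_matches_sums_of_squares_oracle(self, rng):
        data = rng.normal(0, 1, size=(12, 4)) + rng.normal(0, 1, size=(12, 1))
        data[:, 1] += 0.8
        res = stats.rm_anova(data)
        assert res.F == pytest.approx(rm_anova_oracle(data), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.normal(0, 1, size=(10, 4)) + rng.normal(0, 1, size=(10, 1))
        data[:, 2] -= 1.0
        long = pd.DataFrame(
            {
                "y": data.ravel(),
                "cond": np.tile(np.arange(4), 10),
                "subj": np.repeat(np.arange(10), 4),
            }
        )
        out = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
        res = stats.rm_anova(data)
        assert res.F == pytest.approx(float(out["F"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(out["p_unc"].iloc[0]), abs=1e-10)

    def test_degrees_of_freedom_n16_k4(self, rng):
        data = rng.normal(size=(16, 4))
        res = stats.rm_anova(data)
        assert (res.df_num, res.df_den) == (3.0, 45.0)

    def test_k2_f_equals_paired_t_squared(self, rng):
        from scipy.stats import ttest_rel

        data = rng.normal(size=(14, 2))
        data[:, 1] += 0.5
        res = stats.rm_anova(data)
        t = ttest_rel(data[:, 0], data[:, 1]).statistic
        assert res.F == pytest.approx(t**2, abs=1e-9)

    def test_missing_cells_rejected(self):
        data = np.ones((5, 4))
        data[2, 1] = np.nan
        with pytest.raises(InsufficientDataError):
            stats.rm_anova(data)


class TestHelmert:
    def test_coefficients_orthogonal_zero_sum_unit_norm(self):
        C = stats.helmert_coefficients()
        np.testing.assert_allclose(C.sum(axis=1), 0.0, atol=1e-15)
        np.testing.assert_allclose(C @ C.T, np.eye(3), atol=1e-15)

    def test_noiseless_control_shift_loads_only_contrast_one(self):
        data = np.tile([10.0, 6.0, 6.0, 6.0], (8, 1))
        res = stats.helmert_contrasts(data)
        assert res[0].estimate != 0.0
        assert res[1].estimate == pytest.approx(0.0, abs=1e-12)
        assert res[2].estimate == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_per_subject_constant(self, rng):
        data = rng.normal(size=(10, 4))
        shifted = data + rng.normal(0, 5, size=(10, 1))
        for a, b in zip(stats.helmert_contrasts(data), stats.helmert_contrasts(shifted)):
            assert b.estimate == pytest.approx(a.estimate, abs=1e-10)
            assert b.t == pytest.approx(a.t, abs=1e-8)

    def test_wrong_condition_count_rejected(self, rng):
        with pytest.raises(DesignError):
            stats.helmert_contrasts(rng.normal(size=(6, 3)))

    def test_recovery_pattern_power(self):
        """Means (10, 4, 7, 9), subject sd 1, n=16: contrast 1 hits at alpha=.05
        in >= 95% of 500 replicates."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            data = (
                np.array([10.0, 4.0, 7.0, 9.0])
                + rng.normal(0, 1, size=(16, 1))
                + rng.normal(0, 1, size=(16, 4))
            )
            res = stats.helmert_contrasts(data)
            hits += res[0].p < 0.05
        assert hits / n_rep >= 0.95


class TestBatchCompare:
    def _tables(self, rng, metrics, n=15):
        a = pd.DataFrame({m: rng.normal(0, 1, n) for m in metrics})
        b = pd.DataFrame({m: rng.normal(0.5, 1, n) for m in metrics})
        return a, b

    def test_one_comparison_per_metric(self, rng):
        metrics = [f"m{i}" for i in range(7)]
        a, b = self._tables(rng, metrics)
        report = stats.batch_compare(a, b, metrics)
        assert len(report) == 7
        assert list(report["metric"]) == metrics

    def test_unknown_metric_is_config_error(self, rng):
        a, b = self._tables(rng, ["x"])
        with pytest.raises(DesignError):
            stats.batch_compare(a, b, ["x", "nope"])

    def test_holm_correction_optional(self, rng):
        a, b = self._tables(rng, ["x", "y"])
        report = stats.batch_compare(a, b, ["x", "y"], holm=True)
        assert "p_holm" in report.columns
        assert (report["p_holm"] >= report["p"] - 1e-15).all()
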