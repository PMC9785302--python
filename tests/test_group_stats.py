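import numpy as np
import pandas as pd
import pytest
from scipy import stats

import enosekit as ek
from enosekit.group_stats import results_frame


def _vector_with_moments(mean, sd, n, rng=None):
    """A vector whose sample mean/SD equal the given summaries exactly."""
    rng = rng or np.random.default_rng(0)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestFTest:
    def test_terpenes_summaries_select_student_branch(self):
        # SDs 0.8 (n=36) vs 0.9 (n=31): variances statistically equal
        F, p, equal = ek.f_test_variances(summaries=(0.8, 36, 0.9, 31))
        assert F == pytest.approx(0.81 / 0.64, rel=1e-12)
        assert equal
        r = ek.two_group_test_from_summary(1.4, 0.8, 36, 1.4, 0.9, 31)
        assert r.test_used == "student"

    def test_identical_samples(self):
        x = _vector_with_moments(5.0, 1.0, 20)
        F, p, equal = ek.f_test_variances(x, x)
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(1.0)
        assert equal

    def test_large_variance_ratio_detected(self):
        # oracle: direct F CDF evaluation for ratio 100 at n=30 each
        F, p, equal = ek.f_test_variances(summaries=(10.0, 30, 1.0, 30))
        assert F == pytest.approx(100.0)
        assert p == pytest.approx(2 * stats.f.sf(100.0, 29, 29), rel=1e-12)
        assert not equal

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="second"):
            ek.f_test_variances(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestTwoGroupTest:
    def test_identical_groups_null_result(self):
        x = _vector_with_moments(2.0, 0.5, 15)
        r = ek.two_group_test(x, x.copy())
        assert r.t_stat == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_tpc_row_is_welch_significant(self):
        r = ek.two_group_test_from_summary(505, 188, 36, 274, 77, 31)
        assert r.test_used == "welch"
        assert r.p_value < 0.0001
        assert r.letters == ("a", "b")

    def test_dpph_row_is_welch_significant(self):
        r = ek.two_group_test_from_summary(53.2, 17.2, 36, 13.9, 6.4, 31)
        assert r.test_used == "welch"
        assert r.p_value < 0.0001

    @pytest.mark.parametrize(
        "label,row",
        [
            ("aldehydes", (9.8, 9.9, 36, 27.7, 18.0, 31)),
            ("alkenes", (0.4, 0.4, 36, 2.2, 0.9, 31)),
            ("ethers", (0.2, 0.3, 36, 1.1, 0.6, 31)),
            ("alkanes", (1.1, 0.7, 36, 2.9, 1.7, 31)),
            ("total", (14.5, 11.6, 36, 41.6, 19.8, 31)),
        ],
    )
    def test_volatile_class_rows_below_1e4(self, label, row):
        r = ek.two_group_test_from_summary(*row, variable=label)
        assert r.p_value < 0.0001
        assert r.letters == ("b", "a")  # Douro mean larger

    def test_equal_means_give_zero_t(self):
        r = ek.two_group_test_from_summary(3.0, 1.0, 10, 3.0, 4.0, 12)
        assert r.t_stat == pytest.approx(0.0, abs=1e-12)

    def test_raw_equals_summary_route(self):
        rng = np.random.default_rng(7)
        x = rng.normal(5, 2, 25)
        y = rng.normal(4, 1, 30)
        raw = ek.two_group_test(x, y)
        summ = ek.two_group_test_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert raw.t_stat == pytest.approx(summ.t_stat, abs=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)
        assert raw.df == pytest.approx(summ.df, abs=1e-12)
        assert raw.test_used == summ.test_used

    def test_welch_reduces_to_student_under_equal_variances(self):
        # equal sample variances and sizes: identical t, df = n1+n2-2
        x = _vector_with_moments(1.0, 2.0, 20, np.random.default_rng(1))
        y = _vector_with_moments(3.0, 2.0, 20, np.random.default_rng(2))
        t_w, p_w = stats.ttest_ind(x, y, equal_var=False)
        t_s, p_s = stats.ttest_ind(x, y, equal_var=True)
        assert t_w == pytest.approx(t_s, rel=1e-12)
        assert p_w == pytest.approx(p_s, rel=1e-9)
        r = ek.two_group_test(x, y)
        assert r.df == pytest.approx(38, rel=1e-9)

    def test_type_i_error_near_nominal(self):
        # Monte-Carlo oracle: same-distribution groups, rejection ~ alpha
        rng = np.random.default_rng(123)
        reps = 10_000
        x = rng.normal(size=(reps, 20))
        y = rng.normal(size=(reps, 20))
        _, p = stats.ttest_ind(x, y, axis=1)
        # cross-check a handful of replicates against the package battery
        for i in range(5):
            r = ek.two_group_test(x[i], y[i])
            if r.test_used == "student":
                assert r.p_value == pytest.approx(p[i], rel=1e-9)
        rate = np.mean(p < 0.05)
        rejections = sum(
            ek.two_group_test(x[i], y[i]).p_value < 0.05 for i in range(2000)
        )
        assert 0.04 <= rate <= 0.06
        assert 0.03 <= rejections / 2000 <= 0.07


class TestCompareTable:
    def _cohort_frame(self, seed):
        cfg = ek.GeneratorConfig(seed=seed)
        _, profiles, labels = ek.generate_cohort(cfg)
        frame = pd.DataFrame(
            {c: [p.contents[c] for p in profiles] for c in ek.VOLATILE_CLASSES},
            index=labels.index,
        )
        return frame, labels

    def test_table3_significance_pattern_across_cohorts(self):
        non_terpene_sig = {c: 0 for c in ek.VOLATILE_CLASSES if c != "terpenes"}
        terpene_nonsig = 0
        reps = 40
        for seed in range(reps):
            frame, labels = self._cohort_frame(seed)
            for r in ek.compare_table(frame, labels):
                if r.variable == "terpenes":
                    terpene_nonsig += not r.significant
                else:
                    non_terpene_sig[r.variable] += r.significant
        assert terpene_nonsig >= 0.85 * reps
        for c, count in non_terpene_sig.items():
            assert count >= 0.95 * reps, c

    def test_zero_variance_variable_isolated(self):
        frame, labels = self._cohort_frame(1)
        frame["flat"] = 1.0
        results = {r.variable: r for r in ek.compare_table(frame, labels)}
        assert results["flat"].error is not None
        assert results["aldehydes"].error is None
        assert np.isfinite(results["aldehydes"].p_value)

    def test_permutation_invariance(self):
        frame, labels = self._cohort_frame(2)
        perm = np.random.default_rng(0).permutation(len(frame))
        shuffled = frame.iloc[perm]
        a = {r.variable: r.p_value for r in ek.compare_table(frame, labels)}
        b = {
            r.variable: r.p_value
            for r in ek.compare_table(shuffled, labels.iloc[perm])
        }
        for v in a:
            assert a[v] == pytest.approx(b[v], rel=1e-12)

    def test_one_class_rejected(self):
        frame, labels = self._cohort_frame(3)
        with pytest.raises(ValueError, match="two groups"):
            ek.compare_table(frame, pd.Series("Coa", index=labels.index))

    def test_results_frame_has_letters(self):
        frame, labels = self._cohort_frame(4)
        out = results_frame(ek.compare_table(frame, labels))
        assert set(out.columns) >= {"variable", "p", "letter1", "letter2"}
        assert len(out) == len(frame.columns)
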