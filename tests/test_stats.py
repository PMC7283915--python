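"""Comparison layer: one-sample t, ANOVA/Tukey with letters, Pearson."""

import numpy as np
import pytest
from scipy import stats as sps

from droughtmix.stats import (
    FLAG_DEGENERATE,
    FLAG_ZERO_VARIANCE,
    oneway_tukey,
    pearson,
    welch_vs_ref,
)


class TestWelchVsRef:
    def test_matches_textbook_formula(self):
        """p agrees with the direct t = (mean-ref)/(s/sqrt(n)) computation."""
        values = np.array([1.2, 1.3, 1.25, 1.15, 1.3])
        res = welch_vs_ref(values, 1.0)
        n = values.size
        t = (values.mean() - 1.0) / (values.std(ddof=1) / np.sqrt(n))
        p = 2 * sps.t.sf(abs(t), n - 1)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.df == n - 1

    def test_all_equal_to_reference_is_trivial_null(self):
        res = welch_vs_ref([1.0, 1.0, 1.0], 1.0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_variance_off_reference_is_undefined(self):
        res = welch_vs_ref([2.0, 2.0, 2.0], 1.0)
        assert res.flag == FLAG_ZERO_VARIANCE
        assert np.isnan(res.p_value)

    def test_translation_invariance(self):
        vals = np.array([0.2, 0.5, 0.9, 0.4])
        a = welch_vs_ref(vals, 0.3)
        b = welch_vs_ref(vals + 7.0, 7.3)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_too_few_values_flagged(self):
        assert welch_vs_ref([1.0], 0.0).flag is not None


class TestOnewayTukey:
    def test_two_levels_reduce_to_pooled_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        _, grouping = oneway_tukey({"a": a, "b": b})
        t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert grouping.pairwise_p[("a", "b")] == pytest.approx(t_p, abs=1e-10)

    def test_forced_separation_gives_distinct_letters(self):
        rng = np.random.default_rng(0)
        groups = {
            "lo": 0.0 + 1e-3 * rng.normal(size=5),
            "mid": 10.0 + 1e-3 * rng.normal(size=5),
            "hi": 20.0 + 1e-3 * rng.normal(size=5),
        }
        anova, grouping = oneway_tukey(groups)
        assert anova.p_value < 1e-10
        assert len(set(grouping.letters.values())) == 3
        assert all(len(s) == 1 for s in grouping.letters.values())

    def test_indistinguishable_levels_share_a_letter(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(0, 1, 5) for k in "abc"}
        _, grouping = oneway_tukey(groups)
        letters = grouping.letters
        for (i, j), p in grouping.pairwise_p.items():
            shared = set(letters[i]) & set(letters[j])
            if p >= grouping.alpha:
                assert shared, f"{i},{j} not different but share no letter"
            else:
                assert not shared, f"{i},{j} different but share a letter"

    def test_sparse_level_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            anova, grouping = oneway_tukey({"a": [1.0, 2.0, 1.5],
                                            "b": [2.0, 2.5, 2.2],
                                            "c": [9.9]})
        assert "c" not in grouping.letters

    def test_all_identical_data_flagged(self):
        anova, grouping = oneway_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert anova.flag == FLAG_DEGENERATE
        assert set(grouping.letters.values()) == {"a"}

    def test_omnibus_only_mode_skips_grouping(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(0, 1, 5) for k in "abc"}
        anova_full, grouping = oneway_tukey(groups)
        anova_fast, nothing = oneway_tukey(groups, tukey=False)
        assert nothing is None
        assert anova_fast.p_value == anova_full.p_value

    def test_tukey_familywise_error_under_null(self):
        """Any-pair rejection rate under the null stays at or below alpha."""
        rng = np.random.default_rng(2024)
        n_reps = 3000
        false_positives = 0
        for _ in range(n_reps):
            groups = {k: rng.normal(0, 1, 5) for k in "abc"}
            _, grouping = oneway_tukey(groups)
            false_positives += any(p < 0.05 for p in grouping.pairwise_p.values())
        fwer = false_positives / n_reps
        assert fwer <= 0.05 + 0.01 + 2 * np.sqrt(0.05 * 0.95 / n_reps)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        assert pearson(x, x).estimate == pytest.approx(1.0)
        assert pearson(x, -2 * x + 5).estimate == pytest.approx(-1.0)

    def test_fixed_dataset_matches_formula(self):
        x = np.array([1.0, 0.85, 0.70, 0.55, 0.40, 0.25])
        y = np.array([1.08, 1.12, 1.05, 1.21, 1.02, 1.11])
        res = pearson(x, y)
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert res.estimate == pytest.approx(r, abs=1e-14)
        assert res.df == 4
        # p equals the exact t transformation on n-2 df
        t = r * np.sqrt((len(x) - 2) / (1 - r * r))
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), len(x) - 2), abs=1e-12)

    def test_degenerate_variance_flagged(self):
        res = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.flag == FLAG_ZERO_VARIANCE
        assert np.isnan(res.p_value)
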