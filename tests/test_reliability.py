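import numpy as np
import pandas as pd
import pytest

from milenorm.reliability import (
    AGE_GROUP_LABELS,
    ReliabilityError,
    age_groups_series,
    assign_age_group,
    cronbach_alpha,
    descriptives_by_group,
    evaluator_anova,
    spearman_brown,
    split_half_reliability,
)


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age_days, label",
        [
            (0, "0-2"),
            (1825, "54-60"),  # upper boundary: last interval closed
            (200, "6-9"),  # 200 / 30.4375 = 6.57 months
            (60, "0-2"),  # 60 / 30.4375 = 1.97 months
            (61, "2-4"),
        ],
    )
    def test_boundaries(self, age_days, label):
        assert assign_age_group(age_days) == label

    def test_out_of_range(self):
        with pytest.raises(ReliabilityError):
            assign_age_group(1826)
        with pytest.raises(ReliabilityError):
            assign_age_group(-1)

    def test_partition_every_age_maps_once(self):
        """Each age in [0, 1825] maps to exactly one of the 14 groups."""
        ages = pd.Series(np.arange(0, 1826))
        groups = age_groups_series(ages)
        assert groups.notna().all()
        assert set(groups.unique()) <= set(AGE_GROUP_LABELS)
        scalar = ages.map(assign_age_group)
        assert (groups.astype(str) == scalar).all()


class TestCronbachAlpha:
    def test_parallel_items_give_one(self):
        col = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        X = np.column_stack([col] * 5)
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_two_item_worked_matrix(self):
        X = np.array([[1, 1], [1, 0], [0, 0], [0, 1]])
        # item variances 1/3 each; total-score variance 2/3 -> alpha = 0
        assert cronbach_alpha(X) == pytest.approx(0.0, abs=1e-12)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(5000, 20))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_invariances(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(40, 6)).astype(float)
        a = cronbach_alpha(X)
        assert cronbach_alpha(X[:, ::-1]) == pytest.approx(a)  # item reordering
        assert cronbach_alpha(X + 7.0) == pytest.approx(a)  # constant shift

    def test_zero_total_variance(self):
        with pytest.raises(ReliabilityError):
            cronbach_alpha(np.ones((5, 4)))


class TestSplitHalf:
    def test_mirrored_halves(self):
        rng = np.random.default_rng(1)
        half = rng.integers(0, 2, size=(30, 4))
        X = np.column_stack([half, half])  # second half duplicates the first
        raw, sb = split_half_reliability(X, scheme="first_last")
        assert raw == pytest.approx(1.0)
        assert sb == pytest.approx(1.0)

    def test_spearman_brown_formula(self):
        assert spearman_brown(0.5) == pytest.approx(2 * 0.5 / 1.5)
        assert spearman_brown(1.0) == 1.0
        assert spearman_brown(0.8) > spearman_brown(0.5)  # monotone

    def test_odd_even_matches_hand_computation(self):
        X = np.array(
            [[1, 0, 1, 1], [0, 0, 1, 0], [1, 1, 1, 1], [0, 1, 0, 0], [1, 1, 0, 1]],
            dtype=float,
        )
        h1 = X[:, [0, 2]].sum(axis=1)
        h2 = X[:, [1, 3]].sum(axis=1)
        r_hand = (np.mean(h1 * h2) - h1.mean() * h2.mean()) / (
            h1.std() * h2.std()
        )
        raw, sb = split_half_reliability(X, scheme="odd_even")
        assert raw == pytest.approx(r_hand, abs=1e-12)
        assert sb == pytest.approx(2 * r_hand / (1 + r_hand), abs=1e-12)

    def test_random_split_needs_seed(self):
        X = np.random.default_rng(0).integers(0, 2, size=(20, 8))
        with pytest.raises(ReliabilityError):
            split_half_reliability(X, scheme="random")
        r1 = split_half_reliability(X, scheme="random", seed=4)
        assert r1 == split_half_reliability(X, scheme="random", seed=4)


class TestDescriptives:
    def test_degenerate_groups(self):
        scores = pd.DataFrame({"gross_motor": [10, 5, 5, 5]})
        ages = pd.Series([100.0, 400.0, 410.0, 420.0])
        table = descriptives_by_group(scores, ages, min_group_n=2)
        by = table.set_index("age_group")
        assert by.loc["2-4", "n"] == 1
        assert by.loc["2-4", "gross_motor_mean"] == 10
        assert np.isnan(by.loc["2-4", "gross_motor_sd"])
        assert by.loc["2-4", "unreliable"]
        assert by.loc["12-15", "gross_motor_sd"] == 0.0  # identical scores
        assert not by.loc["12-15", "unreliable"]

    def test_empty_dataset(self):
        with pytest.raises(ReliabilityError):
            descriptives_by_group(pd.DataFrame({"s": []}), pd.Series([], dtype=float))


class TestEvaluatorAnova:
    def test_matches_hand_sum_of_squares(self):
        # 3 evaluators x 3 children, all ages in one group
        scores = pd.DataFrame({"gross_motor": [1, 2, 3, 2, 3, 4, 5, 6, 7]})
        ages = pd.Series([400.0] * 9)
        evals = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3])
        out = evaluator_anova(scores, ages, evals)
        cell = out[(out.age_group == "12-15") & out.sufficient].iloc[0]
        groups = [np.array([1, 2, 3]), np.array([2, 3, 4]), np.array([5, 6, 7])]
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ssb / 2) / (ssw / 6)
        assert cell.F == pytest.approx(f_hand, abs=1e-10)
        assert cell.n_evaluators == 3

    def test_identical_evaluators_give_zero_f(self):
        scores = pd.DataFrame({"s": [1, 2, 3, 1, 2, 3]})
        ages = pd.Series([400.0] * 6)
        evals = pd.Series([1, 1, 1, 2, 2, 2])
        out = evaluator_anova(scores, ages, evals)
        cell = out[out.sufficient].iloc[0]
        assert cell.F == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_cells_flagged(self):
        scores = pd.DataFrame({"s": [1, 2]})
        ages = pd.Series([400.0, 410.0])
        evals = pd.Series([1, 2])  # one child each: no cell has 2 evaluators of 2+
        out = evaluator_anova(scores, ages, evals)
        assert not out.sufficient.any()
        assert out.F.isna().all()
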