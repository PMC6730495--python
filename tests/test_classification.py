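"""Split arithmetic, balanced subsampling, metric panel, nested CV, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from neurostage import classification as cl
from neurostage._rng import child_rng

STUDY_SIZES = {"AD": 34, "MCI-C": 25, "MCI-NC": 69, "HC": 49}


def study_labels():
    return np.concatenate([[g] * n for g, n in STUDY_SIZES.items()])


class TestSplitPlan:
    def test_reproduces_printed_partition_sizes(self):
        plan = cl.make_split_plan(study_labels(), seed=0)
        test0 = {str(g): len(v) for g, v in plan.outer_folds[0].items()}
        assert test0 == {"AD": 7, "MCI-C": 5, "MCI-NC": 14, "HC": 10}
        assert len(plan.outer_test(0)) == 36
        assert len(plan.outer_train(0)) == 141
        train0 = {str(g): len(v) for g, v in plan.outer_train_by_group(0).items()}
        assert train0 == {"AD": 27, "MCI-C": 20, "MCI-NC": 55, "HC": 39}
        inner0 = plan.inner_folds[0][0]
        val = {str(g): len(v) for g, v in inner0.items()}
        assert val == {"AD": 5, "MCI-C": 4, "MCI-NC": 11, "HC": 8}
        n_val = sum(val.values())
        assert len(plan.outer_train(0)) - n_val == 113

    def test_folds_partition_each_group(self):
        plan = cl.make_split_plan(study_labels(), seed=3)
        for g, idx in plan.group_indices.items():
            collected = np.concatenate([f[g] for f in plan.outer_folds])
            assert sorted(collected) == sorted(idx)

    def test_no_overlap_between_train_and_test(self):
        plan = cl.make_split_plan(study_labels(), seed=1)
        for f in range(5):
            assert not set(plan.outer_test(f)) & set(plan.outer_train(f))

    def test_group_too_small_rejected(self):
        labels = np.array(["A"] * 4 + ["B"] * 10)
        with pytest.raises(ValueError, match="A"):
            cl.make_split_plan(labels)

    def test_holdout_counts_round_half_up(self):
        assert cl.holdout_counts(STUDY_SIZES) == {
            "AD": 7,
            "MCI-C": 5,
            "MCI-NC": 14,
            "HC": 10,
        }
        assert cl.holdout_counts({g: n for g, n in [("x", 27), ("y", 20), ("z", 55), ("w", 39)]}) == {
            "x": 5, "y": 4, "z": 11, "w": 8,
        }


class TestBalancedSubsample:
    def test_every_group_contributes_n_min(self):
        groups = {
            "AD": np.arange(27),
            "MCI-C": np.arange(100, 120),
            "MCI-NC": np.arange(200, 255),
            "HC": np.arange(300, 339),
        }
        sub = cl.balanced_subsample(groups, child_rng(0, "s"))
        assert len(sub) == 80                    # 4 x 20 (the smallest group)
        for idx in groups.values():
            assert np.isin(sub, idx).sum() == 20

    def test_equal_groups_identity_up_to_order(self):
        groups = {"a": np.arange(5), "b": np.arange(10, 15)}
        sub = cl.balanced_subsample(groups, child_rng(1, "s"))
        assert sorted(sub) == sorted(np.concatenate(list(groups.values())))

    def test_sub_seed_determinism(self):
        groups = {"a": np.arange(30), "b": np.arange(50, 70)}
        s1 = cl.balanced_subsample(groups, child_rng(5, "rep", 0))
        s2 = cl.balanced_subsample(groups, child_rng(5, "rep", 0))
        s3 = cl.balanced_subsample(groups, child_rng(5, "rep", 1))
        assert (s1 == s2).all()
        assert sorted(s1) != sorted(s3)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array(["a", "b", "a", "b"])
        scores = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        rep = cl.confusion_metrics(y, y, ["a", "b"], scores)
        assert rep.overall_accuracy == 100.0
        assert (rep.per_class["sensitivity"] == 100.0).all()
        assert (rep.per_class["specificity"] == 100.0).all()
        assert (rep.per_class["ppv"] == 100.0).all()
        assert (rep.per_class["auc"] == 1.0).all()

    def test_two_class_arithmetic(self):
        # confusion [[8,2],[3,7]]: sens 80%, spec 70%, PPV 8/11
        y_true = np.array(["p"] * 10 + ["n"] * 10)
        y_pred = np.array(["p"] * 8 + ["n"] * 2 + ["p"] * 3 + ["n"] * 7)
        rep = cl.confusion_metrics(y_true, y_pred, ["p", "n"])
        assert rep.per_class.loc["p", "sensitivity"] == pytest.approx(80.0)
        assert rep.per_class.loc["p", "specificity"] == pytest.approx(70.0)
        assert rep.per_class.loc["p", "ppv"] == pytest.approx(100 * 8 / 11)
        assert rep.per_class.loc["p", "accuracy"] == pytest.approx(80.0)
        assert rep.overall_accuracy == pytest.approx(75.0)

    def test_never_predicted_class_ppv_nan(self):
        y_true = np.array(["a", "b", "a", "b"])
        y_pred = np.array(["a", "a", "a", "a"])
        with pytest.warns(UserWarning, match="never predicted"):
            rep = cl.confusion_metrics(y_true, y_pred, ["a", "b"])
        assert np.isnan(rep.per_class.loc["b", "ppv"])

    def test_confusion_rows_sum_to_100(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c"]
        y_true = rng.choice(classes, 300)
        y_pred = rng.choice(classes, 300)
        rep = cl.confusion_metrics(y_true, y_pred, classes)
        np.testing.assert_allclose(rep.confusion_percent.sum(axis=1), 100.0)


class TestChanceLevels:
    def test_uniform_random_four_and_three_group(self):
        rng = np.random.default_rng(7)
        n = 100_000
        for k, expected in ((4, 25.0), (3, 100.0 / 3)):
            y = rng.integers(0, k, n)
            pred = rng.integers(0, k, n)
            acc = 100.0 * np.mean(y == pred)
            sd = 100.0 * np.sqrt((1 / k) * (1 - 1 / k) / n)
            assert abs(acc - expected) < 4 * sd


class TestNestedCv:
    def _feature_matrix(self, rng, informative=True, n_per=12):
        labels = np.repeat(["AD", "HC", "MCI-C", "MCI-NC"], n_per)
        y_num = np.repeat(np.arange(4), n_per)
        x = rng.normal(size=(len(labels), 12))
        if informative == "oracle":
            x[:, 0] = y_num                    # the label fed as a feature
        elif informative:
            x[:, :3] += y_num[:, None] * 2.0
        data = pd.DataFrame(
            x,
            index=[f"s{i}" for i in range(len(labels))],
            columns=[f"f{j}" for j in range(12)],
        )
        return data, pd.Series(labels, index=data.index)

    def test_oracle_leak_reaches_100(self, rng):
        data, labels = self._feature_matrix(rng, informative="oracle")
        rep = cl.nested_cv_classify(
            data, labels, cl.NestedCvConfig(k_max=4, n_reps=3), seed=0
        )
        assert rep.overall_accuracy == 100.0

    def test_pure_noise_near_chance(self, rng):
        data, labels = self._feature_matrix(rng, informative=False, n_per=15)
        rep = cl.nested_cv_classify(
            data, labels, cl.NestedCvConfig(k_max=4, n_reps=20), seed=1
        )
        # 60 distinct test subjects; 3-sigma binomial band around 25%
        sd = 100.0 * np.sqrt(0.25 * 0.75 / 60)
        assert abs(rep.overall_accuracy - 25.0) < 3 * sd

    def test_selection_ignores_test_fold_content(self, rng):
        data, labels = self._feature_matrix(rng)
        plan = cl.make_split_plan(labels.to_numpy(), seed=5)
        test0 = plan.outer_test(0)
        corrupted = data.copy()
        corrupted.iloc[test0] = rng.normal(size=(len(test0), data.shape[1])) * 100
        rep1 = cl.nested_cv_classify(
            data, labels, cl.NestedCvConfig(k_max=4, n_reps=1), seed=5
        )
        rep2 = cl.nested_cv_classify(
            corrupted, labels, cl.NestedCvConfig(k_max=4, n_reps=1), seed=5
        )
        assert rep1.selection_log[0] == rep2.selection_log[0]

    def test_three_group_subset(self, rng):
        data, labels = self._feature_matrix(rng)
        rep = cl.nested_cv_classify(
            data,
            labels,
            cl.NestedCvConfig(k_max=3, n_reps=2),
            seed=2,
            groups_to_use=["AD", "MCI-C", "MCI-NC"],
        )
        assert rep.classes == ["AD", "MCI-C", "MCI-NC"]
        assert rep.confusion_counts.shape == (3, 3)


class TestGroupAnova:
    def test_identical_groups_f_zero(self):
        f = pd.DataFrame({"x": [1.0, 2, 3, 1, 2, 3]}, index=list("abcdef"))
        labels = pd.Series(["g1"] * 3 + ["g2"] * 3, index=f.index)
        out = cl.group_anova(f, labels)
        assert out.loc["x", "F"] == pytest.approx(0.0)
        assert out.loc["x", "p"] == pytest.approx(1.0)

    def test_textbook_three_group_instance(self):
        # groups (1,2,3), (2,3,4), (4,5,6): SSB = 3*((2-3.333)^2+(3-3.333)^2
        # +(5-3.333)^2) = 14, SSW = 6, F = (14/2)/(6/6) = 7
        vals = [1.0, 2, 3, 2, 3, 4, 4, 5, 6]
        f = pd.DataFrame({"x": vals}, index=[f"s{i}" for i in range(9)])
        labels = pd.Series(
            ["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=f.index
        )
        out = cl.group_anova(f, labels)
        assert out.loc["x", "F"] == pytest.approx(7.0)

    def test_shifting_a_group_increases_f(self, rng):
        base = rng.normal(size=30)
        idx = [f"s{i}" for i in range(30)]
        labels = pd.Series(["a"] * 15 + ["b"] * 15, index=idx)
        prev = 0.0
        for shift in (0.5, 1.0, 2.0):
            vals = base.copy()
            vals[15:] += shift
            out = cl.group_anova(pd.DataFrame({"x": vals}, index=idx), labels)
            assert out.loc["x", "F"] > prev
            prev = out.loc["x", "F"]

    def test_degenerate_inputs_rejected(self):
        f = pd.DataFrame({"x": [1.0, 1, 1, 1]}, index=list("abcd"))
        labels = pd.Series(["a"] * 2 + ["b"] * 2, index=f.index)
        with pytest.raises(ValueError):
            cl.group_anova(f, labels)


class TestDcaSelector:
    def test_dca_route_runs_and_beats_chance_on_separated_data(self, rng):
        from neurostage.morphometry import FeatureMatrix
        import pandas as pd

        labels = np.repeat(["AD", "HC", "MCI-C", "MCI-NC"], 12)
        y_num = np.repeat(np.arange(4), 12)
        x = rng.normal(size=(48, 10))
        # each class gets its own mean direction in both modality blocks
        mean_dirs = rng.normal(size=(4, 10)) * 2.5
        x += mean_dirs[y_num]
        idx = [f"s{i}" for i in range(48)]
        cols = [f"f{j}" for j in range(10)]
        fm = FeatureMatrix(
            data=pd.DataFrame(x, index=idx, columns=cols),
            modality=pd.Series(["rsfmri"] * 5 + ["smri"] * 5, index=cols),
            groups=pd.Series(labels, index=idx),
            normalization={},
        )
        rep = cl.nested_cv_classify(
            fm, config=cl.NestedCvConfig(selector="dca", n_reps=3), seed=0
        )
        # well above the 25% chance level (3-sigma band on 48 subjects)
        assert rep.overall_accuracy > 25.0 + 3 * 100 * np.sqrt(0.25 * 0.75 / 48)
        assert all(s["size"] <= 3 for s in rep.selection_log)

    def test_dca_requires_modality_tags(self, rng):
        import pandas as pd

        labels = pd.Series(np.repeat(["AD", "HC", "MCI-C", "MCI-NC"], 12))
        data = pd.DataFrame(rng.normal(size=(48, 6)))
        labels.index = data.index
        with pytest.raises(ValueError, match="modality"):
            cl.nested_cv_classify(
                data, labels, cl.NestedCvConfig(selector="dca", n_reps=1), seed=0
            )


def test_repetition_count_robustness(rng):
    # averaged accuracy is stable in the number of balanced-subsample
    # repetitions: 1,000 vs 100 differ by well under 2 points
    labels = np.repeat(["AD", "HC", "MCI-C", "MCI-NC"], 15)
    y_num = np.repeat(np.arange(4), 15)
    x = rng.normal(size=(60, 8))
    x += (rng.normal(size=(4, 8)) * 1.2)[y_num]
    data = pd.DataFrame(
        x, index=[f"s{i}" for i in range(60)], columns=[f"f{j}" for j in range(8)]
    )
    lab = pd.Series(labels, index=data.index)
    accs = {}
    for reps in (100, 1000):
        rep = cl.nested_cv_classify(
            data, lab, cl.NestedCvConfig(k_max=4, n_reps=reps), seed=3
        )
        accs[reps] = rep.overall_accuracy
    assert abs(accs[100] - accs[1000]) < 2.0
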