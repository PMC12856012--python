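import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crayfish_sexing.preprocessing import (
    TABLE1_FOLD_COUNTS,
    FoldPlan,
    ImputeStrategy,
    apply_scaler,
    assign_folds,
    clip_outliers_iqr,
    fit_scaler,
    impute,
    preprocess_image,
)
from crayfish_sexing.synthetic import MorphometricTable, TabularSimSpec, generate_tabular


def make_table(values, labels=None):
    values = np.asarray(values, dtype=float)
    mask = np.isnan(values)
    if labels is None:
        labels = np.array(["F", "M"] * values.shape[0])[: values.shape[0]]
    names = [f"f{j}" for j in range(values.shape[1])]
    return MorphometricTable(values, mask, labels, names)


class TestImpute:
    def test_no_missing_returned_unchanged(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0]])
        out = impute(t, ImputeStrategy("mean"))
        np.testing.assert_array_equal(out.values, t.values)

    @pytest.mark.parametrize(
        "kind,expected",
        [("mean", 2.0), ("median", 2.0), ("mode", 1.0)],
    )
    def test_single_column_fill_values(self, kind, expected):
        t = make_table([[1.0], [2.0], [np.nan], [3.0], [1.0]])
        out = impute(t, ImputeStrategy(kind))
        # mean of {1,2,3,1} = 1.75 -- adjust column per strategy
        if kind == "mean":
            assert out.values[2, 0] == pytest.approx(1.75)
        elif kind == "median":
            assert out.values[2, 0] == 1.5
        else:
            assert out.values[2, 0] == expected  # smallest modal value

    def test_forced_mean_example(self):
        t = make_table([[1.0], [2.0], [np.nan], [3.0]])
        out = impute(t, ImputeStrategy("mean"))
        assert out.values[2, 0] == 2.0
        assert not out.missing_mask.any()

    def test_mode_tie_breaks_to_smallest(self):
        t = make_table([[2.0], [2.0], [1.0], [1.0], [np.nan]])
        out = impute(t, ImputeStrategy("mode"))
        assert out.values[4, 0] == 1.0

    def test_knn_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(5, 3))
        values[1, 2] = np.nan
        t = make_table(values.copy())
        out = impute(t, ImputeStrategy("knn", k=2))
        # brute force: distances over commonly observed features
        dists = []
        for r in range(5):
            if r == 1:
                dists.append(np.inf)
                continue
            common = ~np.isnan(values[1]) & ~np.isnan(values[r])
            dists.append(np.linalg.norm(values[1, common] - values[r, common]))
        order = np.argsort(dists)
        donors = [r for r in order if not np.isnan(values[r, 2])][:2]
        assert out.values[1, 2] == pytest.approx(np.mean(values[donors, 2]))

    def test_observed_cells_never_altered(self):
        t = generate_tabular(TabularSimSpec(20, 20, missing_rate=0.2, seed=2))
        for kind in ("mean", "median", "mode", "knn"):
            out = impute(t, ImputeStrategy(kind))
            obs = ~t.missing_mask
            np.testing.assert_array_equal(out.values[obs], t.values[obs])
            assert not out.missing_mask.any()

    def test_all_missing_feature_named_in_error(self):
        t = make_table([[np.nan, 1.0], [np.nan, 2.0]])
        with pytest.raises(ValueError, match="f0"):
            impute(t, ImputeStrategy("mean"))


class TestIqrCapping:
    def test_hand_computed_example(self):
        t = make_table([[v] for v in [1.0, 2.0, 3.0, 4.0, 100.0]],
                       labels=np.array(["F"] * 5))
        out = clip_outliers_iqr(t, multiplier=3)
        # Q1=2, Q3=4 (linear interpolation), IQR=2 -> fence [-4, 10]
        np.testing.assert_array_equal(out.values[:, 0], [1, 2, 3, 4, 10])

    def test_constant_column_unchanged(self):
        t = make_table([[5.0]] * 4)
        out = clip_outliers_iqr(t)
        np.testing.assert_array_equal(out.values, t.values)

    def test_inlier_column_identity(self):
        t = make_table([[v] for v in [1.0, 2.0, 3.0, 4.0, 5.0]],
                       labels=np.array(["F"] * 5))
        np.testing.assert_array_equal(clip_outliers_iqr(t).values, t.values)

    def test_missing_cells_rejected(self):
        t = make_table([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="imputed"):
            clip_outliers_iqr(t)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=5, max_size=40),
           st.floats(0.5, 5.0))
    def test_idempotence(self, col, mult):
        t = make_table([[v] for v in col], labels=np.array(["F"] * len(col)))
        once = clip_outliers_iqr(t, mult)
        twice = clip_outliers_iqr(once, mult)
        np.testing.assert_allclose(twice.values, once.values, rtol=0, atol=0)


class TestScaler:
    def test_standard_forced_example(self):
        train = make_table([[1.0], [3.0]])
        state = fit_scaler(train, "standard")
        assert state.center[0] == 2.0 and state.scale[0] == 1.0
        scaled = apply_scaler(state, train)
        np.testing.assert_array_equal(scaled.values[:, 0], [-1.0, 1.0])
        test = make_table([[2.0]], labels=np.array(["F"]))
        assert apply_scaler(state, test).values[0, 0] == 0.0

    def test_minmax_forced_example(self):
        train = make_table([[2.0], [4.0], [6.0]], labels=np.array(["F"] * 3))
        state = fit_scaler(train, "minmax")
        np.testing.assert_array_equal(
            apply_scaler(state, train).values[:, 0], [0.0, 0.5, 1.0]
        )

    def test_minmax_no_clipping_outside_train_range(self):
        train = make_table([[0.0], [10.0]])
        state = fit_scaler(train, "minmax")
        test = make_table([[12.0]], labels=np.array(["F"]))
        assert apply_scaler(state, test).values[0, 0] == pytest.approx(1.2)

    def test_train_moments_identities(self):
        t = generate_tabular(TabularSimSpec(30, 30, seed=8))
        std = apply_scaler(fit_scaler(t, "standard"), t)
        np.testing.assert_allclose(std.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(std.values.std(axis=0), 1, atol=1e-9)
        mm = apply_scaler(fit_scaler(t, "minmax"), t)
        np.testing.assert_allclose(mm.values.min(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(mm.values.max(axis=0), 1, atol=1e-9)

    def test_constant_feature_warns_not_raises(self):
        t = make_table([[1.0, 5.0], [2.0, 5.0]])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            state = fit_scaler(t, "standard")
        assert any("constant" in str(w.message) for w in caught)
        assert state.scale[1] == 1.0

    def test_feature_set_mismatch_rejected(self):
        state = fit_scaler(make_table([[1.0], [2.0]]), "standard")
        other = MorphometricTable(np.zeros((1, 1)), np.zeros((1, 1), bool),
                                  np.array(["F"]), ["different"])
        with pytest.raises(ValueError, match="feature set"):
            apply_scaler(state, other)


class TestFoldPlan:
    def test_study_fold_table_reproduced(self):
        labels = np.array(["F"] * 62 + ["M"] * 50)
        plan = assign_folds(labels, seed=4)
        for fold, (f, m) in enumerate(TABLE1_FOLD_COUNTS):
            idx = plan.test_indices(fold)
            assert int(np.sum(labels[idx] == "F")) == f
            assert int(np.sum(labels[idx] == "M")) == m
        assert len(plan.test_indices(0)) == 12  # 7 F + 5 M
        assert len(plan.test_indices(7)) == 11  # 4 F + 7 M

    def test_balanced_case_one_per_class_per_fold(self):
        labels = np.array(["F", "M"] * 10)
        plan = assign_folds(labels, n_folds=10, seed=0)
        for fold in range(10):
            idx = plan.test_indices(fold)
            assert int(np.sum(labels[idx] == "F")) == 1
            assert int(np.sum(labels[idx] == "M")) == 1

    def test_round_robin_matches_enumeration_oracle(self):
        labels = np.array(["F"] * 23 + ["M"] * 17)
        plan = assign_folds(labels, n_folds=10, seed=1)
        # oracle: dealing n items to 10 folds cyclically
        for sex, n in (("F", 23), ("M", 17)):
            expected = [n // 10 + (1 if i < n % 10 else 0) for i in range(10)]
            got = [int(np.sum(labels[plan.test_indices(f)] == sex))
                   for f in range(10)]
            assert got == expected
            assert max(got) - min(got) <= 1

    def test_partition_property(self):
        labels = np.array(["F"] * 31 + ["M"] * 19)
        plan = assign_folds(labels, n_folds=7, seed=3)
        seen = np.concatenate([plan.test_indices(f) for f in range(7)])
        assert sorted(seen) == list(range(50))

    def test_inconsistent_targets_rejected(self):
        labels = np.array(["F"] * 4 + ["M"] * 4)
        bad = [{"F": 3, "M": 2}, {"F": 3, "M": 2}]
        with pytest.raises(ValueError, match="sum"):
            assign_folds(labels, n_folds=2, target_counts=bad)


class TestImagePreprocess:
    def test_uniform_extremes(self):
        white = np.full((40, 40), 255, dtype=np.uint8)
        np.testing.assert_allclose(preprocess_image(white), 1.0)
        mid = np.full((40, 40), 0.5)
        np.testing.assert_allclose(preprocess_image(mid), 0.0, atol=1e-12)

    def test_checkerboard_bilinear_oracle(self):
        # 1-pixel checkerboard at 56x56: every output sample sits at the
        # centre of a 2x2 block with two 0s and two 1s -> 0.5 -> 0 after
        # the affine map.  2-pixel checkerboard: blocks align with output
        # pixels -> values stay {0, 1} -> {-1, +1}.
        fine = np.indices((56, 56)).sum(axis=0) % 2
        out = preprocess_image(fine.astype(float))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)
        coarse = ((np.indices((56, 56))[0] // 2 +
                   np.indices((56, 56))[1] // 2) % 2).astype(float)
        out2 = preprocess_image(coarse)
        assert set(np.round(np.unique(out2), 12)) == {-1.0, 1.0}

    def test_rgb_luminance_and_resize_shape(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, (56, 84, 3), dtype=np.uint8)
        out = preprocess_image(rgb)
        assert out.shape == (28, 28)
        assert out.min() >= -1.0 - 1e-9 and out.max() <= 1.0 + 1e-9

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            preprocess_image(np.zeros((0, 0)))
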