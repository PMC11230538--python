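"""Model families, balancing, LOSO protocol and metrics."""

import dataclasses
import datetime

import numpy as np
import pandas as pd
import pytest

from sleepsense.dataset import FEATURE_NAMES, drop_missing
from sleepsense.modeling import (ALL_GROUP_SUBSETS, ModelSpec, ablation,
                                 balance_by_downsampling, fit_model, loso_cv,
                                 metrics, _normalized_fold)
from sleepsense.signal_io import ValidationError
from sleepsense.synthetic import CohortSpec, simulate_observations


def _train_frame(X, y):
    df = pd.DataFrame(X, columns=FEATURE_NAMES)
    df["label"] = y
    df["participant_id"] = "P"
    df["night_date"] = datetime.date(2024, 1, 1)
    df["response"] = 3
    return df


class TestBalance:
    def _obs(self, labels):
        df = pd.DataFrame({"label": labels})
        return df

    def test_downsample_to_minority(self, rng):
        df = self._obs([1] * 10 + [0] * 6)
        out = balance_by_downsampling(df, rng)
        assert out["label"].value_counts().tolist() == [6, 6]

    def test_already_balanced_is_identity(self, rng):
        df = self._obs([1, 0, 1, 0])
        out = balance_by_downsampling(df, rng)
        pd.testing.assert_frame_equal(out, df)

    def test_seeded_removal_is_reproducible(self):
        df = self._obs([1] * 10 + [0] * 4)
        a = balance_by_downsampling(df, np.random.default_rng(3))
        b = balance_by_downsampling(df, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)


class TestFitModel:
    def test_all_families_separate_separable_toy(self, rng):
        X = rng.normal(size=(60, 52))
        y = (X[:, 0] > 0).astype(int)
        train = _train_frame(X, y)
        for family in ("tree_ensemble", "glm", "gam"):
            m = fit_model(ModelSpec(family=family), train)
            assert (m.predict(train) == y).mean() == 1.0

    def test_single_class_train_rejected(self, rng):
        train = _train_frame(rng.normal(size=(10, 52)), np.ones(10, dtype=int))
        with pytest.raises(ValidationError):
            fit_model(ModelSpec(), train)

    def test_glm_orthogonal_feature_has_null_coefficient(self, rng):
        n = 500
        X = rng.normal(size=(n, 52))
        y = (X[:, 1] + rng.normal(0, 0.5, n) > 0).astype(int)
        m = fit_model(ModelSpec(family="glm"), _train_frame(X, y))
        coef = m._impl.coef_[0][0]
        # feature 0 is independent of the labels; the asymptotic 2-SE band
        # for a unit-variance logit predictor at n=500 is about +-0.25
        assert abs(coef) < 0.35

    def test_tree_ensemble_seeded_reproducible(self, rng):
        X = rng.normal(size=(80, 52))
        y = rng.integers(0, 2, size=80)
        train = _train_frame(X, y)
        m1 = fit_model(ModelSpec(seed=7), train)
        m2 = fit_model(ModelSpec(seed=7), train)
        np.testing.assert_array_equal(m1.predict_proba(train), m2.predict_proba(train))

    def test_subset_spec_selects_act_plus_groups(self):
        spec = ModelSpec(feature_groups=frozenset())
        assert sorted(spec.features) == sorted(
            ["sleep_duration_min", "sleep_onset_latency_min",
             "counts_awake_sum", "counts_asleep_sum"])
        spec = ModelSpec(feature_groups=frozenset({"TEMP"}))
        assert len(spec.features) == 16


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = metrics(y, y.astype(float))
        assert m == {"ba": 1.0, "micro_f1": 1.0, "auc": 1.0}

    def test_inverted_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = metrics(y, 1.0 - y)
        assert m["ba"] == 0.0 and m["auc"] == 0.0

    def test_hand_built_table(self):
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        y_prob = np.array([0.9, 0.8, 0.4, 0.3, 0.6, 0.2, 0.1, 0.2])
        m = metrics(y_true, y_prob)
        # recalls: high 2/4, low 3/4 -> BA 0.625; accuracy 5/8
        assert m["ba"] == pytest.approx(0.625)
        assert m["micro_f1"] == pytest.approx(5 / 8)
        # rank AUC: 14 of the 16 (pos, neg) pairs rank correctly
        assert m["auc"] == pytest.approx(14 / 16)

    def test_ba_equals_accuracy_on_balanced_test(self, rng):
        y = np.array([0, 1] * 20)
        p = rng.random(40)
        m = metrics(y, p)
        acc = np.mean((p >= 0.5).astype(int) == y)
        assert m["ba"] == pytest.approx(acc)
        assert m["micro_f1"] == pytest.approx(acc)


@pytest.fixture(scope="module")
def small_ds():
    spec = CohortSpec(n_participants=5, n_nights=12, seed=23)
    obs, _ = simulate_observations(spec)
    return drop_missing(obs)


class TestLOSO:
    def test_split_count_and_holdout_multiplicity(self, small_ds):
        res = loso_cv(small_ds, ModelSpec(family="glm"), n_repeats=3, seed=1,
                      labeling="normalized")
        assert res.n_splits == 15
        assert (res.holdout_counts() == 3).all()

    def test_normalized_fold_is_fold_pure(self, small_ds):
        obs = small_ds.observations
        pids = sorted(obs["participant_id"].unique())
        train1, test1 = _normalized_fold(
            obs[obs["participant_id"] != pids[0]],
            obs[obs["participant_id"] == pids[0]])
        train2, _ = _normalized_fold(
            obs[obs["participant_id"] != pids[1]],
            obs[obs["participant_id"] == pids[1]])
        # no held-out rows in training
        assert pids[0] not in train1["participant_id"].tolist()
        # held-out labels derive only from the held-out participant's data
        own = obs[obs["participant_id"] == pids[0]]
        expected = (own["response"].to_numpy() >= own["response"].mean()).astype(int)
        np.testing.assert_array_equal(test1["label"].to_numpy(), expected)

    def test_label_noise_only_gives_chance_ba(self):
        spec = CohortSpec(n_participants=8, n_nights=40, seed=29,
                          label_coeffs={"sleep_duration_min": 0.0},
                          label_noise_sd=1.0)
        obs, _ = simulate_observations(spec)
        ds = drop_missing(obs)
        res = loso_cv(ds, ModelSpec(family="glm"), n_repeats=1, seed=2,
                      labeling="normalized")
        assert 0.35 <= res.aggregates["ba"] <= 0.65

    def test_fewer_than_two_participants_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 52)), columns=FEATURE_NAMES)
        df["participant_id"] = "only"
        df["night_date"] = datetime.date(2024, 1, 1)
        df["response"] = [1, 5, 2, 4, 3, 5]
        ds = drop_missing(df)
        with pytest.raises(ValidationError):
            loso_cv(ds, ModelSpec(family="glm"))


class TestHRVAdjustmentInFolds:
    def test_window_table_adjustment_is_fold_pure(self, rng, small_ds):
        """With a cardiac window table, the stratified HRV reference is
        refit per fold and rewrites the 18 HRV aggregate features."""
        obs = small_ds.observations
        pids = sorted(obs["participant_id"].unique())
        rows = []
        for _, r in obs.iterrows():
            for k in range(12):
                rows.append({
                    "participant_id": r["participant_id"],
                    "night_date": r["night_date"],
                    "start": 3600.0 * k,
                    "phase": "awake" if k < 6 else "asleep",
                    "hr": rng.normal(70, 5), "rmssd": rng.normal(40, 10),
                    "sdnn": rng.normal(55, 12), "sd2": rng.normal(70, 15),
                    "n_beats": 300,
                })
        window_table = pd.DataFrame(rows)
        demo = pd.DataFrame({"participant_id": pids,
                             "age": [25 + i for i in range(len(pids))],
                             "gender": ["F", "M"] * (len(pids) // 2) +
                                       ["M"] * (len(pids) % 2)})
        res = loso_cv(small_ds, ModelSpec(family="glm"), n_repeats=1, seed=4,
                      labeling="normalized", window_table=window_table,
                      demographics=demo)
        assert res.n_splits == len(pids)

        from sleepsense.cardiac import AdjustmentReference
        from sleepsense.modeling import _adjust_cardiac_features
        refs = []
        for held_out in pids[:2]:
            ref = AdjustmentReference().fit(
                window_table[window_table["participant_id"] != held_out]
                .merge(demo, on="participant_id", how="left"))
            refs.append(ref)
        # the training reference changes when the held-out participant does
        assert refs[0]._pooled["rmssd"] != refs[1]._pooled["rmssd"]
        adjusted = _adjust_cardiac_features(obs, window_table, demo, refs[0])
        assert not np.allclose(adjusted["rmssd_mean_awake"],
                               obs["rmssd_mean_awake"])


class TestAblation:
    def test_grid_shape_and_act_always_included(self):
        spec = CohortSpec(n_participants=4, n_nights=10, seed=31)
        obs, _ = simulate_observations(spec)
        ds = drop_missing(obs)
        table = ablation(ds, ModelSpec(), families=("glm",), n_repeats=1,
                        seed=3, labeling="normalized")
        assert len(table) == 8
        assert set(table["groups"]) == {
            "CAR+EDA+TEMP", "CAR+TEMP", "CAR+EDA", "CAR",
            "EDA+TEMP", "TEMP", "EDA", "(none)"}
        assert len(ALL_GROUP_SUBSETS) == 8

    def test_signal_bearing_groups_dominate(self):
        spec = CohortSpec(n_participants=8, n_nights=25, seed=37,
                          label_coeffs={"hr_mean_awake": 2.0},
                          label_noise_sd=0.3)
        obs, _ = simulate_observations(spec)
        ds = drop_missing(obs)
        table = ablation(ds, ModelSpec(), families=("glm",), n_repeats=1,
                         seed=5, labeling="normalized").set_index("groups")
        with_car = table.loc[["CAR+EDA+TEMP", "CAR+TEMP", "CAR+EDA", "CAR"], "ba"].mean()
        without_car = table.loc[["EDA+TEMP", "TEMP", "EDA", "(none)"], "ba"].mean()
        assert with_car > without_car + 0.1
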