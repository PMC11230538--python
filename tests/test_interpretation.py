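"""Partial dependence, importance and misclassification diagnostics."""

import datetime

import numpy as np
import pandas as pd
import pytest

from sleepsense.dataset import FEATURE_NAMES, LabeledDataset, drop_missing
from sleepsense.interpretation import (PDPCurve, bootstrap_pdp,
                                       feature_importance,
                                       misclassification_curve, pdp)
from sleepsense.modeling import EvaluationResult, ModelSpec
from sleepsense.synthetic import CohortSpec, simulate_observations


class _StumpModel:
    """P(high) = p_hi if feature > threshold else p_lo."""

    def __init__(self, feature, threshold, p_lo=0.3, p_hi=0.7):
        self.features = list(FEATURE_NAMES)
        self.feature = feature
        self.threshold = threshold
        self.p_lo, self.p_hi = p_lo, p_hi

    def predict_proba(self, X):
        v = X[self.feature].to_numpy(dtype=float)
        return np.where(v > self.threshold, self.p_hi, self.p_lo)


class _IgnoringModel:
    def __init__(self):
        self.features = list(FEATURE_NAMES)

    def predict_proba(self, X):
        return np.full(len(X), 0.5)


def _data(rng, n=300):
    df = pd.DataFrame(rng.normal(size=(n, 52)), columns=FEATURE_NAMES)
    return df


class TestPDP:
    def test_ignored_feature_flat_zero(self, rng):
        curve = pdp(_IgnoringModel(), _data(rng), FEATURE_NAMES[0])
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-12)

    def test_stump_step_at_split(self, rng):
        f = FEATURE_NAMES[0]
        data = _data(rng)
        curve = pdp(_StumpModel(f, threshold=0.0), data, f, center=False)
        below = curve.values[curve.grid <= 0.0]
        above = curve.values[curve.grid > 0.0]
        np.testing.assert_allclose(below, 0.3)
        np.testing.assert_allclose(above, 0.7)

    def test_centering_mean_zero(self, rng):
        f = FEATURE_NAMES[3]
        curve = pdp(_StumpModel(f, 0.5), _data(rng), f)
        assert abs(np.mean(curve.values)) < 1e-12

    def test_grid_strictly_increasing_enforced(self):
        with pytest.raises(Exception):
            PDPCurve("x", np.array([0.0, 0.0, 1.0]), np.zeros(3))


@pytest.fixture(scope="module")
def planted_ds():
    spec = CohortSpec(n_participants=6, n_nights=20, seed=43,
                      label_coeffs={"sleep_duration_min": 2.0},
                      label_noise_sd=0.3)
    obs, _ = simulate_observations(spec)
    from sleepsense.dataset import normalize_per_participant
    return normalize_per_participant(drop_missing(obs))


class TestBootstrap:
    def test_b1_single_curve(self, planted_ds):
        curves, means = bootstrap_pdp(planted_ds, ModelSpec(family="glm"),
                                      ["sleep_duration_min"], B=1, seed=5)
        assert len(curves["sleep_duration_min"]) == 1
        np.testing.assert_allclose(curves["sleep_duration_min"][0].values,
                                   means["sleep_duration_min"].values)

    def test_seeded_determinism(self, planted_ds):
        _, m1 = bootstrap_pdp(planted_ds, ModelSpec(family="glm"),
                              ["sleep_duration_min"], B=5, seed=5)
        _, m2 = bootstrap_pdp(planted_ds, ModelSpec(family="glm"),
                              ["sleep_duration_min"], B=5, seed=5)
        np.testing.assert_array_equal(m1["sleep_duration_min"].values,
                                      m2["sleep_duration_min"].values)

    def test_planted_positive_effect_monotone(self, planted_ds):
        curves, means = bootstrap_pdp(planted_ds, ModelSpec(family="glm"),
                                      ["sleep_duration_min"], B=20, seed=5)
        frac = np.mean([c.is_nondecreasing() for c in curves["sleep_duration_min"]])
        assert frac >= 0.9

    def test_band_contains_full_data_curve(self, planted_ds):
        from sleepsense.modeling import fit_model, balance_by_downsampling
        spec = ModelSpec(family="tree_ensemble", n_estimators=100)
        curves, means = bootstrap_pdp(planted_ds, spec,
                                      ["sleep_duration_min"], B=30, seed=5)
        rng = np.random.default_rng(0)
        full = fit_model(spec, balance_by_downsampling(planted_ds.observations, rng))
        ref = pdp(full, planted_ds.observations, "sleep_duration_min",
                  grid=means["sleep_duration_min"].grid)
        stack = np.vstack([c.values for c in curves["sleep_duration_min"]])
        lo, hi = stack.min(axis=0), stack.max(axis=0)
        covered = np.mean((ref.values >= lo) & (ref.values <= hi))
        assert covered >= 0.8


class TestImportance:
    def test_ignored_feature_zero(self, rng):
        grid = np.linspace(-1, 1, 20)
        curves = {FEATURE_NAMES[0]: PDPCurve(FEATURE_NAMES[0], grid, np.zeros(20))}
        table = feature_importance(curves, _data(rng))
        assert table["importance"].iloc[0] == 0.0

    def test_stump_importance_half_jump(self, rng):
        f = FEATURE_NAMES[0]
        data = _data(rng, n=20000)
        curve = pdp(_StumpModel(f, 0.0, p_lo=0.3, p_hi=0.7), data, f)
        table = feature_importance({f: curve}, data)
        # centered curve is +-delta/2 around 0 under a symmetric density
        assert table["importance"].iloc[0] == pytest.approx(0.2, abs=0.02)


def test_permutation_importance_ranks_used_feature_first(rng):
    from sleepsense.interpretation import permutation_feature_importance
    f = FEATURE_NAMES[0]
    data = _data(rng, n=400)
    labels = (data[f] > 0).astype(int)
    table = permutation_feature_importance(_StumpModel(f, 0.0, 0.0, 1.0),
                                           data, labels, n_repeats=5, seed=1)
    assert table["feature"].iloc[0] == f
    assert table["importance"].iloc[0] > 0.3
    assert (table["importance"].iloc[1:] == 0.0).all()


class TestErrorCurves:
    def _result(self, errs, values, feature):
        n = len(errs)
        obs = pd.DataFrame({
            "participant_id": ["p"] * n,
            "night_date": [datetime.date(2024, 1, 1) + datetime.timedelta(days=i)
                           for i in range(n)],
            feature: values,
        })
        y_true = np.zeros(n, dtype=int)
        y_pred = errs.astype(int)  # error wherever y_pred != 0
        records = pd.DataFrame({
            "participant_id": obs["participant_id"],
            "repeat": 0,
            "night_date": obs["night_date"],
            "y_true": y_true,
            "y_prob": y_pred.astype(float),
            "y_pred": y_pred,
        })
        result = EvaluationResult(records=records, n_splits=1, skipped=[],
                                  spec=ModelSpec(), labeling="normalized",
                                  variant="A")
        return result, obs

    def test_uniform_errors_not_flagged(self, rng):
        errs = rng.random(400) < 0.3
        values = rng.normal(size=400)
        result, obs = self._result(errs, values, FEATURE_NAMES[0])
        curve = misclassification_curve(result, obs, FEATURE_NAMES[0])
        assert abs(curve.rho) < 0.2 and not curve.clear_trend

    def test_concentrated_errors_flagged_negative(self, rng):
        values = rng.normal(size=400)
        errs = values < -0.5  # mistakes at low feature values
        result, obs = self._result(errs, values, FEATURE_NAMES[0])
        curve = misclassification_curve(result, obs, FEATURE_NAMES[0])
        assert curve.rho < 0 and curve.clear_trend

    def test_all_correct_flat_zero(self, rng):
        values = rng.normal(size=100)
        errs = np.zeros(100, dtype=bool)
        result, obs = self._result(errs, values, FEATURE_NAMES[0])
        curve = misclassification_curve(result, obs, FEATURE_NAMES[0])
        np.testing.assert_allclose(curve.smoothed, 0.0, atol=1e-12)

    def test_noise_features_flag_more_often_than_signal(self, rng):
        """Errors tied to a noise feature raise its trend flag above a
        feature the classifier actually uses correctly."""
        n = 500
        signal = rng.normal(size=n)
        noise = rng.normal(size=n)
        # errors increase with the noise feature, independent of the signal
        errs = rng.random(n) < (0.1 + 0.5 * (noise > 0.5))
        result, obs = self._result(errs, signal, FEATURE_NAMES[0])
        obs[FEATURE_NAMES[1]] = noise
        c_signal = misclassification_curve(result, obs, FEATURE_NAMES[0])
        c_noise = misclassification_curve(result, obs, FEATURE_NAMES[1])
        assert abs(c_noise.rho) > abs(c_signal.rho)
        assert c_noise.clear_trend and not c_signal.clear_trend
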