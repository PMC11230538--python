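"""Model families and repeated leave-one-participant-out evaluation.

Three explainable families predict the binary sleep-quality label: a bagged
randomized-tree ensemble (random-forest style: 500 trees, sqrt feature
subsampling, depth cap 6), an unpenalized logistic regression (GLM) and a
logistic additive model with per-feature cubic-spline smooths (GAM).

Evaluation is leave-one-participant-out cross-validation repeated 10 times:
each split trains on all other participants and tests on the held-out one,
with train and test sets independently class-balanced by random
downsampling.  Under normalized labeling, the per-participant normalization
statistics are computed inside the training fold for training participants
and from the held-out participant's own data alone for the test fold, so no
held-out information ever reaches training.  Aggregate metrics (balanced
accuracy, micro-F1, AUC) are computed on the pooled per-split predictions.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, f1_score, roc_auc_score

from .cardiac import AdjustmentReference
from .dataset import (FEATURE_NAMES, GROUP_FEATURES, LabeledDataset,
                      apply_normalization, participant_statistics)
from .signal_io import ValidationError

__all__ = [
    "ModelSpec",
    "EvaluationResult",
    "FittedModel",
    "balance_by_downsampling",
    "fit_model",
    "loso_cv",
    "metrics",
    "ablation",
    "ALL_GROUP_SUBSETS",
]

FAMILIES = ("tree_ensemble", "glm", "gam")

#: The 8 ablation subsets of {CAR, TEMP, EDA}; actigraphy is always included.
ALL_GROUP_SUBSETS: Tuple[frozenset, ...] = tuple(
    frozenset(s) for s in (
        {"CAR", "TEMP", "EDA"}, {"CAR", "TEMP"}, {"CAR", "EDA"}, {"CAR"},
        {"TEMP", "EDA"}, {"TEMP"}, {"EDA"}, set(),
    )
)


@dataclasses.dataclass
class ModelSpec:
    """One model configuration: family, feature groups and hyperparameters."""

    family: str = "tree_ensemble"
    feature_groups: frozenset = frozenset({"CAR", "TEMP", "EDA"})
    seed: int = 0
    n_estimators: int = 500
    max_depth: int = 6
    gam_df: int = 10
    gam_degree: int = 3
    gam_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown model family {self.family!r}")
        self.feature_groups = frozenset(self.feature_groups)
        unknown = self.feature_groups - {"CAR", "TEMP", "EDA"}
        if unknown:
            raise ValidationError(f"unknown feature groups {sorted(unknown)}")

    @property
    def features(self) -> List[str]:
        """Actigraphy features plus the selected groups, in canonical order."""
        groups = {"ACT"} | set(self.feature_groups)
        return [f for f in FEATURE_NAMES if f in
                {n for g in groups for n in GROUP_FEATURES[g]}]


class FittedModel:
    """A fitted classifier exposing P(high sleep quality)."""

    def __init__(self, family: str, features: List[str], impl, extra=None):
        self.family = family
        self.features = features
        self._impl = impl
        self._extra = extra or {}

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Z = np.asarray(X[self.features], dtype=float)
        if self.family == "tree_ensemble":
            return self._impl.predict_proba(Z)[:, list(self._impl.classes_).index(1)]
        if self.family == "glm":
            return self._impl.predict_proba(Z)[:, list(self._impl.classes_).index(1)]
        # gam: statsmodels GLMGam result (or its ridge-penalized fallback)
        smoother = self._extra["smoother"]
        Zc = np.clip(Z, self._extra["lo"], self._extra["hi"])
        exog_smooth = smoother.transform(Zc)
        if self._extra.get("ridge"):
            return self._impl.predict_proba(exog_smooth)[:, list(self._impl.classes_).index(1)]
        exog = np.column_stack([np.ones(len(Zc)), exog_smooth])
        return np.asarray(self._impl.model.family.link.inverse(exog @ self._impl.params))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def _split_rng(seed: int, repeat: int, participant_id: str) -> np.random.Generator:
    crc = zlib.crc32(str(participant_id).encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, int(repeat), crc])


def balance_by_downsampling(observations: pd.DataFrame,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Equalize label counts by randomly removing from the larger class."""
    counts = observations["label"].value_counts()
    if len(counts) < 2:
        return observations.iloc[0:0]
    n_min = int(counts.min())
    parts = []
    for label, grp in observations.groupby("label"):
        if len(grp) > n_min:
            idx = rng.choice(grp.index.to_numpy(), size=n_min, replace=False)
            parts.append(observations.loc[np.sort(idx)])
        else:
            parts.append(grp)
    return pd.concat(parts).sort_index()


def fit_model(spec: ModelSpec, train: pd.DataFrame) -> FittedModel:
    """Fit one model family on a labeled training table."""
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data contains a single class")
    X = np.asarray(train[spec.features], dtype=float)
    if spec.family == "tree_ensemble":
        impl = RandomForestClassifier(
            n_estimators=spec.n_estimators, max_depth=spec.max_depth,
            max_features="sqrt", random_state=spec.seed & 0x7FFFFFFF,
            n_jobs=1,
        ).fit(X, y)
        return FittedModel(spec.family, spec.features, impl)
    if spec.family == "glm":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            # C=inf: unpenalized maximum-likelihood logistic fit
            impl = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
        return FittedModel(spec.family, spec.features, impl)
    # gam: logistic additive model, cubic B-spline smooth per feature
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    smoother = BSplines(X, df=[spec.gam_df] * X.shape[1],
                        degree=[spec.gam_degree] * X.shape[1],
                        include_intercept=False)
    exog = np.ones((len(X), 1))
    extra = {"smoother": smoother, "lo": lo + 1e-12 * span,
             "hi": hi - 1e-12 * span}
    n_basis = smoother.dim_basis
    if n_basis < 0.8 * len(X):
        # the curvature-penalized PIRLS fit is well-posed; if the logistic
        # likelihood still separates, escalate the penalty before giving up
        for alpha in (spec.gam_alpha, spec.gam_alpha * 1e2, spec.gam_alpha * 1e4):
            model = GLMGam(y, exog=exog, smoother=smoother,
                           alpha=[alpha] * X.shape[1],
                           family=sm.families.Binomial())
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(maxiter=50)
                return FittedModel(spec.family, spec.features, res, extra=extra)
            except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
                continue
    # more smooth-term parameters than observations support: same additive
    # spline basis, ridge-penalized logistic fit
    basis = smoother.transform(np.clip(X, extra["lo"], extra["hi"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ridge = LogisticRegression(C=1.0, max_iter=2000).fit(basis, y)
    extra["ridge"] = True
    return FittedModel(spec.family, spec.features, ridge, extra=extra)


def metrics(y_true: np.ndarray, y_prob: np.ndarray,
            y_pred: Optional[np.ndarray] = None) -> Dict[str, float]:
    """Balanced accuracy, micro-F1 and AUC of pooled predictions."""
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_pred is None:
        y_pred = (y_prob >= 0.5).astype(int)
    out = {
        "ba": float(balanced_accuracy_score(y_true, y_pred)),
        "micro_f1": float(f1_score(y_true, y_pred, average="micro")),
    }
    out["auc"] = (float(roc_auc_score(y_true, y_prob))
                  if len(np.unique(y_true)) == 2 else float("nan"))
    return out


@dataclasses.dataclass
class EvaluationResult:
    """Per-split predictions and pooled metrics of one LOSO evaluation."""

    records: pd.DataFrame     # participant, repeat, y_true, y_prob, y_pred
    n_splits: int
    skipped: List[Tuple[int, str, str]]
    spec: ModelSpec
    labeling: str
    variant: str

    @property
    def aggregates(self) -> Dict[str, float]:
        if len(self.records) == 0:
            return {"ba": float("nan"), "micro_f1": float("nan"), "auc": float("nan")}
        return metrics(self.records["y_true"].to_numpy(),
                       self.records["y_prob"].to_numpy(),
                       self.records["y_pred"].to_numpy())

    def holdout_counts(self) -> pd.Series:
        """How many splits each participant was held out in."""
        return (self.records[["participant_id", "repeat"]]
                .drop_duplicates()
                .groupby("participant_id")["repeat"].size())


def _normalized_fold(train_obs: pd.DataFrame, test_obs: pd.DataFrame):
    """Fold-pure per-participant normalization: training statistics come from
    the training fold, held-out statistics from the held-out data alone."""
    train_stats = participant_statistics(train_obs)
    test_stats = participant_statistics(test_obs)
    return (apply_normalization(train_obs, train_stats),
            apply_normalization(test_obs, test_stats))


def _eligible_for_normalization(obs: pd.DataFrame) -> pd.DataFrame:
    ok = obs.groupby("participant_id")["response"].transform(
        lambda r: (len(r) >= 2) and (r.nunique() >= 2))
    return obs[ok.astype(bool)]


def _adjust_cardiac_features(obs: pd.DataFrame, window_table: pd.DataFrame,
                             demographics: pd.DataFrame,
                             reference: AdjustmentReference) -> pd.DataFrame:
    """Rebuild the 18 HRV aggregate features from stratum-adjusted windows."""
    wt = window_table.merge(demographics, on="participant_id", how="left")
    adj = wt.copy()
    for metric in AdjustmentReference.ADJUSTED:
        adj[metric] = [
            reference.adjust(v, metric, g, a, s)
            for v, g, a, s in zip(wt[metric], wt["gender"], wt["age"], wt["start"])
        ]
    out = obs.copy()
    # aggregate adjusted windows back to per-night features needs the phase
    # split, which the window table carries via the 'phase' column
    if "phase" not in adj.columns:
        return out
    for (pid, date), grp in adj.groupby(["participant_id", "night_date"]):
        sel = (out["participant_id"] == pid) & (out["night_date"] == date)
        if not sel.any():
            continue
        for phase in ("awake", "asleep"):
            pg = grp[grp["phase"] == phase]
            for metric in AdjustmentReference.ADJUSTED:
                for stat, fn in (("mean", np.mean), ("max", np.max), ("min", np.min)):
                    name = f"{metric}_{stat}_{phase}"
                    if len(pg):
                        out.loc[sel, name] = float(fn(pg[metric].to_numpy()))
    return out


def loso_cv(dataset: LabeledDataset, spec: ModelSpec, n_repeats: int = 10,
            seed: int = 0, labeling: Optional[str] = None,
            window_table: Optional[pd.DataFrame] = None,
            demographics: Optional[pd.DataFrame] = None) -> EvaluationResult:
    """Repeated leave-one-participant-out evaluation with class balancing.

    ``dataset`` should carry raw (absolute-labeled) observations; pass
    ``labeling='normalized'`` to apply fold-pure per-participant
    normalization inside each split.  When a cardiac ``window_table`` and
    participant ``demographics`` are given, the HRV adjustment reference is
    refit on training participants' windows for every split.
    """
    labeling = labeling or dataset.labeling
    obs = dataset.observations
    if obs["participant_id"].nunique() < 2:
        raise ValidationError("LOSO needs at least 2 participants")
    if labeling == "normalized":
        obs = _eligible_for_normalization(obs)
    participants = sorted(obs["participant_id"].unique())
    records = []
    skipped: List[Tuple[int, str, str]] = []
    for repeat in range(n_repeats):
        for pid in participants:
            rng = _split_rng(seed, repeat, pid)
            train_obs = obs[obs["participant_id"] != pid].reset_index(drop=True)
            test_obs = obs[obs["participant_id"] == pid].reset_index(drop=True)
            if window_table is not None and demographics is not None:
                ref = AdjustmentReference().fit(
                    window_table[window_table["participant_id"] != pid]
                    .merge(demographics, on="participant_id", how="left"))
                train_obs = _adjust_cardiac_features(train_obs, window_table,
                                                     demographics, ref)
                test_obs = _adjust_cardiac_features(test_obs, window_table,
                                                    demographics, ref)
            if labeling == "normalized":
                train_obs, test_obs = _normalized_fold(train_obs, test_obs)
            train_bal = balance_by_downsampling(train_obs, rng)
            test_bal = balance_by_downsampling(test_obs, rng)
            if len(test_bal) < 2:
                skipped.append((repeat, pid, "test fold too small after balancing"))
                continue
            if train_bal["label"].nunique() < 2:
                skipped.append((repeat, pid, "single-class training fold"))
                continue
            model = fit_model(dataclasses.replace(spec, seed=spec.seed + repeat),
                              train_bal)
            prob = model.predict_proba(test_bal)
            for (_, row), p in zip(test_bal.iterrows(), prob):
                records.append({
                    "participant_id": pid, "repeat": repeat,
                    "night_date": row["night_date"],
                    "y_true": int(row["label"]), "y_prob": float(p),
                    "y_pred": int(p >= 0.5),
                })
    rec_df = pd.DataFrame(records, columns=["participant_id", "repeat",
                                            "night_date", "y_true", "y_prob",
                                            "y_pred"])
    n_splits = n_repeats * len(participants) - len(skipped)
    return EvaluationResult(records=rec_df, n_splits=n_splits, skipped=skipped,
                            spec=spec, labeling=labeling, variant=dataset.variant)


def ablation(dataset: LabeledDataset, spec_template: ModelSpec,
             families: Sequence[str] = FAMILIES,
             subsets: Sequence[frozenset] = ALL_GROUP_SUBSETS,
             n_repeats: int = 10, seed: int = 0,
             labeling: Optional[str] = None) -> pd.DataFrame:
    """Grid of LOSO evaluations over families x feature-group subsets.

    Actigraphy features are included in every cell; the empty subset is the
    actigraphy-only model.
    """
    rows = []
    for family in families:
        for subset in subsets:
            spec = dataclasses.replace(spec_template, family=family,
                                       feature_groups=frozenset(subset))
            result = loso_cv(dataset, spec, n_repeats=n_repeats, seed=seed,
                             labeling=labeling)
            agg = result.aggregates
            rows.append({
                "family": family,
                "groups": "+".join(sorted(subset)) if subset else "(none)",
                "variant": dataset.variant,
                "ba": agg["ba"], "auc": agg["auc"],
                "n_splits": result.n_splits,
            })
    return pd.DataFrame(rows)
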