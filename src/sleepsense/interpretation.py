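"""Partial dependence, bootstrapped stability, importance and error curves.

A partial dependence plot (PDP) sweeps one feature over a grid while holding
every other feature at its observed values and averages the predicted
probability of high sleep quality; curves are centered to mean zero over the
grid so that only the *shape* of the effect is read.  Stability is assessed
by refitting the classifier on bootstrap resamples (100 by default) and
overlaying the resulting curves.  Feature importance is the data-density-
weighted mean absolute value of the centered mean PDP — the average change
in predicted probability attributable to the feature.  Misclassification
curves smooth the per-observation error indicator along a feature axis; a
clear monotone trend there signals a decision function that does not
generalize (overfitting to that feature).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dataset import LabeledDataset
from .modeling import (EvaluationResult, FittedModel, ModelSpec,
                       balance_by_downsampling, fit_model)
from .signal_io import ValidationError

__all__ = [
    "PDPCurve",
    "ErrorCurve",
    "pdp",
    "bootstrap_pdp",
    "feature_importance",
    "permutation_feature_importance",
    "misclassification_curve",
    "TREND_RHO_THRESHOLD",
]

#: |Spearman rho| above which an error curve is flagged as a clear trend.
TREND_RHO_THRESHOLD = 0.2

#: Tie tolerance when testing a PDP for monotonicity: tree-ensemble PDPs are
#: step functions, so adjacent grid values may jitter by a hair.
MONOTONE_TOL = 1e-3


@dataclasses.dataclass
class PDPCurve:
    """Partial dependence of the predicted probability on one feature."""

    feature: str
    grid: np.ndarray
    values: np.ndarray
    centered: bool = True

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.grid) != len(self.values):
            raise ValidationError("grid and values must align")
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("PDP grid must be strictly increasing")

    def is_nondecreasing(self, central_frac: float = 0.8,
                         tol: float = MONOTONE_TOL) -> bool:
        """Monotone over the central fraction of the grid (tie tolerance)."""
        n = len(self.grid)
        k = int(round(n * (1 - central_frac) / 2))
        central = self.values[k: n - k]
        return bool(np.all(np.diff(central) >= -tol))


@dataclasses.dataclass
class ErrorCurve:
    """Smoothed misclassification proportion along one feature axis."""

    feature: str
    grid: np.ndarray
    raw_rate: np.ndarray
    smoothed: np.ndarray
    rho: float
    clear_trend: bool


def make_grid(values: np.ndarray, n_grid: int = 20,
              pct: tuple = (5.0, 95.0)) -> np.ndarray:
    lo, hi = np.percentile(values, pct)
    if hi <= lo:
        hi = lo + 1e-9
    return np.linspace(lo, hi, n_grid)


def pdp(model: FittedModel, data: pd.DataFrame, feature: str,
        grid: Optional[np.ndarray] = None, n_grid: int = 20,
        center: bool = True) -> PDPCurve:
    """Partial dependence of P(high) on one feature.

    ``PD(v) = mean_i P(high | feature := v, other features of i fixed)``,
    evaluated on a 20-point grid between the 5th and 95th percentile of the
    observed feature values, then centered to mean zero.
    """
    if feature not in model.features:
        raise ValidationError(f"model does not use feature {feature!r}")
    if grid is None:
        grid = make_grid(data[feature].to_numpy(dtype=float), n_grid)
    base = data[model.features]
    stacked = pd.concat([base] * len(grid), ignore_index=True)
    stacked[feature] = np.repeat(grid, len(base))
    probs = model.predict_proba(stacked).reshape(len(grid), len(base))
    values = probs.mean(axis=1)
    if center:
        values = values - values.mean()
    return PDPCurve(feature=feature, grid=np.asarray(grid), values=values,
                    centered=center)


def bootstrap_pdp(dataset: LabeledDataset, spec: ModelSpec,
                  features: Sequence[str], B: int = 100, seed: int = 0,
                  balance: bool = True, n_grid: int = 20,
                  eval_rows: Optional[int] = None):
    """Refit the classifier on ``B`` bootstrap resamples; centered PDPs.

    Grids are fixed from the full data so curves are pointwise comparable.
    Each refit's PDP is evaluated on the full data (resample-refit,
    full-data-evaluation); ``eval_rows`` optionally caps the number of
    background rows the partial dependence averages over (a seeded subsample,
    for large panels).  Returns ``(curves, mean_curves)`` where curves maps
    feature -> list of per-replicate curves and mean_curves maps feature ->
    the pointwise mean curve.
    """
    if isinstance(features, str):
        features = [features]
    obs = dataset.observations
    grids = {f: make_grid(obs[f].to_numpy(dtype=float), n_grid) for f in features}
    curves: Dict[str, List[PDPCurve]] = {f: [] for f in features}
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 313131])
    eval_obs = obs
    if eval_rows is not None and eval_rows < len(obs):
        pick = rng.choice(len(obs), size=eval_rows, replace=False)
        eval_obs = obs.iloc[np.sort(pick)].reset_index(drop=True)
    for b in range(B):
        idx = rng.integers(0, len(obs), size=len(obs))
        sample = obs.iloc[idx].reset_index(drop=True)
        if balance:
            sample = balance_by_downsampling(sample, rng)
        if sample["label"].nunique() < 2:
            continue
        model = fit_model(dataclasses.replace(spec, seed=spec.seed + b), sample)
        for f in features:
            curves[f].append(pdp(model, eval_obs, f, grid=grids[f]))
    mean_curves = {}
    for f in features:
        if curves[f]:
            stack = np.vstack([c.values for c in curves[f]])
            mean_curves[f] = PDPCurve(feature=f, grid=grids[f],
                                      values=stack.mean(axis=0))
    return curves, mean_curves


def feature_importance(mean_curves: Dict[str, PDPCurve],
                       data: pd.DataFrame) -> pd.DataFrame:
    """Density-weighted mean |centered PDP| per feature, ranked descending.

    The weight of each grid point is the fraction of observed values nearest
    to it, so regions the data actually occupies dominate the score.
    """
    rows = []
    for f, curve in mean_curves.items():
        v = data[f].to_numpy(dtype=float)
        edges = np.concatenate((
            [-np.inf],
            (curve.grid[1:] + curve.grid[:-1]) / 2.0,
            [np.inf],
        ))
        counts, _ = np.histogram(v, bins=edges)
        weights = counts / counts.sum() if counts.sum() else np.ones(len(curve.grid)) / len(curve.grid)
        rows.append({"feature": f,
                     "importance": float(np.sum(weights * np.abs(curve.values)))})
    table = pd.DataFrame(rows).sort_values("importance", ascending=False)
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def permutation_feature_importance(model: FittedModel, data: pd.DataFrame,
                                   labels: np.ndarray, n_repeats: int = 10,
                                   seed: int = 0) -> pd.DataFrame:
    """Alternative importance: accuracy drop under feature permutation.

    Each feature column is shuffled ``n_repeats`` times and the mean drop in
    accuracy relative to the intact data is reported.
    """
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    y = np.asarray(labels, dtype=int)
    base = float(np.mean((model.predict_proba(data) >= 0.5).astype(int) == y))
    rows = []
    for f in model.features:
        drops = []
        for _ in range(n_repeats):
            shuffled = data.copy()
            shuffled[f] = rng.permutation(shuffled[f].to_numpy())
            acc = float(np.mean((model.predict_proba(shuffled) >= 0.5).astype(int) == y))
            drops.append(base - acc)
        rows.append({"feature": f, "importance": max(0.0, float(np.mean(drops)))})
    table = pd.DataFrame(rows).sort_values("importance", ascending=False)
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    if sigma <= 0:
        sigma = 1.0
    return 0.9 * sigma * n ** (-1 / 5)


def misclassification_curve(result: EvaluationResult,
                            observations: pd.DataFrame, feature: str,
                            n_grid: int = 40) -> ErrorCurve:
    """Misclassification proportion along one feature's axis.

    Cross-validated predictions are joined to the observations by
    participant and night; the error indicator is smoothed with a Gaussian
    kernel (Silverman's bandwidth).  The Spearman correlation between the
    feature value and the error indicator is reported; |rho| above 0.2
    flags a clear trend.
    """
    joined = result.records.merge(
        observations[["participant_id", "night_date", feature]],
        on=["participant_id", "night_date"], how="inner")
    if len(joined) == 0:
        raise ValidationError("no predictions could be joined to observations")
    x = joined[feature].to_numpy(dtype=float)
    err = (joined["y_true"] != joined["y_pred"]).to_numpy(dtype=float)
    grid = make_grid(x, n_grid, pct=(2.0, 98.0))
    bw = _silverman_bandwidth(x)
    w = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bw) ** 2)
    smoothed = (w @ err) / np.maximum(w.sum(axis=1), 1e-12)
    # raw binned proportions for reference
    edges = np.concatenate(([-np.inf], (grid[1:] + grid[:-1]) / 2.0, [np.inf]))
    which = np.digitize(x, edges) - 1
    raw = np.full(len(grid), np.nan)
    for g in range(len(grid)):
        m = which == g
        if m.any():
            raw[g] = float(err[m].mean())
    if len(np.unique(x)) > 1 and len(np.unique(err)) > 1:
        rho = float(spearmanr(x, err).statistic)
    else:
        rho = 0.0
    rho = rho if np.isfinite(rho) else 0.0
    return ErrorCurve(feature=feature, grid=grid, raw_rate=raw,
                      smoothed=np.clip(smoothed, 0.0, 1.0), rho=rho,
                      clear_trend=bool(abs(rho) > TREND_RHO_THRESHOLD))


def plot_pdp_panel(curves: Dict[str, List[PDPCurve]],
                   mean_curves: Dict[str, PDPCurve], path=None):
    """Fig-style panel: gray per-bootstrap curves, blue mean curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    feats = list(mean_curves)
    ncols = 4
    nrows = max(1, int(np.ceil(len(feats) / ncols)))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows),
                             squeeze=False)
    for ax, f in zip(axes.ravel(), feats):
        for c in curves.get(f, []):
            ax.plot(c.grid, c.values, color="0.7", lw=0.5, alpha=0.5)
        mc = mean_curves[f]
        ax.plot(mc.grid, mc.values, color="deepskyblue", lw=2)
        ax.axhline(0.0, color="k", lw=0.5, ls=":")
        ax.set_title(f, fontsize=8)
    for ax in axes.ravel()[len(feats):]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
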