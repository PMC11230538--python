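"""Per-night observations, dataset variants A/B, labeling and diagnostics.

One observation is one night: a named 52-feature vector (24 cardiac, 12 EDA,
12 temperature, 4 actigraphy) plus the 1-5 Likert response and the
participant/date identity.  Variant A derives cardiac features from the
device's own inter-beat intervals; variant B from beats detected in the raw
BVP.  Observations with any missing value are removed — never imputed — and
participants left with no observations leave the roster.

Two labelings of the binary response are supported: *absolute* (response
>= 4 means high sleep quality for everyone) and *normalized* (each night is
compared with that participant's personal mean response; features are
z-scored within participant).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import cardiac as _cardiac
from . import eda as _eda
from . import temperature as _temp
from .actigraphy import (SleepPeriodMissing, activity_counts,
                         actigraphy_features, estimate_sleep_period,
                         score_sleep_wake)
from .signal_io import RecordingSession, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "GROUP_FEATURES",
    "ID_COLUMNS",
    "LabeledDataset",
    "build_daily_observation",
    "build_observations",
    "drop_missing",
    "binarize_absolute",
    "normalize_per_participant",
    "label_balance_report",
    "variance_decomposition",
]

ID_COLUMNS = ["participant_id", "night_date", "response"]

_STATS = ("mean", "max", "min")
_PHASES = ("awake", "asleep")

#: Canonical feature inventory: 24 cardiac + 12 EDA + 12 temperature + 4
#: actigraphy = 52 named features, with their group tags.
FEATURE_GROUPS: Dict[str, str] = {}
for _metric in _cardiac.CARDIAC_METRICS:
    for _stat in _STATS:
        for _phase in _PHASES:
            FEATURE_GROUPS[f"{_metric}_{_stat}_{_phase}"] = "CAR"
for _kind in ("level", "slope"):
    for _stat in _STATS:
        for _phase in _PHASES:
            FEATURE_GROUPS[f"eda_{_kind}_{_stat}_{_phase}"] = "EDA"
            FEATURE_GROUPS[f"temp_{_kind}_{_stat}_{_phase}"] = "TEMP"
for _name in ("sleep_duration_min", "sleep_onset_latency_min",
              "counts_awake_sum", "counts_asleep_sum"):
    FEATURE_GROUPS[_name] = "ACT"

FEATURE_NAMES: List[str] = list(FEATURE_GROUPS)
assert len(FEATURE_NAMES) == 52

GROUP_FEATURES: Dict[str, List[str]] = {}
for _n, _g in FEATURE_GROUPS.items():
    GROUP_FEATURES.setdefault(_g, []).append(_n)


@dataclasses.dataclass
class LabeledDataset:
    """Complete observations plus binary labels for one variant/labeling.

    ``observations`` has the identity columns, the 52 features and a binary
    ``label`` column (1 = high sleep quality).  For normalized labeling,
    ``participant_stats`` holds the per-participant mean/SD used for the
    feature z-scores and the mean response that sets the personal cutoff.
    """

    observations: pd.DataFrame
    variant: str
    labeling: str
    participant_stats: Optional[pd.DataFrame] = None
    removal_report: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.variant not in ("A", "B"):
            raise ValidationError(f"variant must be 'A' or 'B', got {self.variant!r}")
        if self.labeling not in ("absolute", "normalized"):
            raise ValidationError(f"unknown labeling {self.labeling!r}")
        feats = self.observations[FEATURE_NAMES]
        if feats.isna().any().any():
            raise ValidationError("a labeled dataset cannot contain missing values")

    @property
    def participants(self) -> List[str]:
        return sorted(self.observations["participant_id"].unique())

    def __len__(self) -> int:
        return len(self.observations)


def _estimate_period(session: RecordingSession):
    counts = activity_counts(session.channels["ACC"])
    series = score_sleep_wake(counts)
    return estimate_sleep_period(series, session.diary), counts


def build_daily_observation(session: RecordingSession, sleep_period=None,
                            variant: str = "A",
                            return_windows: bool = False):
    """Assemble one night's 52-feature vector.

    The asleep phase is the estimated ``[onset, wake)``; the awake phase is
    all in-session time outside the sleep period within the 24 hours
    preceding wake.  Features of an absent channel — and every feature when
    the sleep period cannot be estimated — are missing (NaN).
    """
    row: Dict[str, object] = {
        "participant_id": session.participant_id,
        "night_date": session.night_date,
        "response": session.diary.sleep_quality if session.diary else np.nan,
    }
    for name in FEATURE_NAMES:
        row[name] = np.nan

    counts = None
    if sleep_period is None:
        try:
            if "ACC" not in session.channels:
                raise SleepPeriodMissing("no ACC channel")
            sleep_period, counts = _estimate_period(session)
        except SleepPeriodMissing:
            return (row, []) if return_windows else row
    awake_window = (sleep_period.wake - 24 * 3600.0, sleep_period.wake)

    window_records: List[Dict[str, object]] = []
    ibis = None
    if variant == "A":
        ibis = session.device_ibis
    elif "BVP" in session.channels:
        filtered = _cardiac.bandpass_bvp(session.channels["BVP"])
        ibis = _cardiac.detect_beats(filtered)
    if ibis is not None and len(ibis):
        ref = next(iter(session.channels.values()))
        windows = _cardiac.window_ibis(ibis, t0=ref.start_time, t_end=ref.end_time)
        row.update(_cardiac.aggregate_cardiac(windows, sleep_period, awake_window))
        from .signal_io import phase_masks
        for w in windows:
            if not w.quality_ok:
                continue
            mid = np.array([w.start + w.duration / 2.0])
            awake, asleep = phase_masks(mid, sleep_period.onset,
                                        sleep_period.wake, awake_window)
            phase = "asleep" if asleep[0] else ("awake" if awake[0] else "excluded")
            window_records.append({
                "participant_id": session.participant_id,
                "night_date": session.night_date,
                "start": w.start, "phase": phase, "hr": w.hr,
                "rmssd": w.rmssd, "sdnn": w.sdnn, "sd2": w.sd2,
                "n_beats": w.n_beats,
            })

    if "EDA" in session.channels:
        rec = session.channels["EDA"]
        mask = _eda.validate_eda(rec)
        row.update(_eda.eda_features(rec, mask, sleep_period,
                                     awake_window=awake_window))
    if "TEMP" in session.channels:
        row.update(_temp.temp_features(session.channels["TEMP"], sleep_period,
                                       awake_window=awake_window))
    if "ACC" in session.channels:
        if counts is None:
            counts = activity_counts(session.channels["ACC"])
        row.update(actigraphy_features(counts, sleep_period, awake_window))
    return (row, window_records) if return_windows else row


def build_observations(sessions: List[RecordingSession], variant: str = "A",
                       collect_windows: bool = False):
    """Feature table over many sessions (one row per night).

    With ``collect_windows`` a per-window cardiac metrics table is returned
    as well, for the HRV adjustment reference and for audit output.
    """
    rows = []
    window_rows: List[Dict[str, object]] = []
    for session in sessions:
        row, wrecs = build_daily_observation(session, variant=variant,
                                             return_windows=True)
        rows.append(row)
        if collect_windows:
            window_rows.extend(wrecs)
    obs = pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_NAMES)
    if collect_windows:
        return obs, pd.DataFrame(window_rows)
    return obs


def binarize_absolute(response) -> np.ndarray:
    """High sleep quality iff the Likert response is 4 or 5."""
    r = np.asarray(response)
    if np.any((r < 1) | (r > 5)):
        raise ValidationError("responses must lie in 1..5")
    return (r >= 4).astype(int)


def drop_missing(observations: pd.DataFrame, variant: str = "A") -> LabeledDataset:
    """Remove observations with any missing value; empty participants leave
    the roster.  Labels are the absolute (>= 4) binarization; a removal
    report with per-participant retained counts is attached."""
    feats = observations[FEATURE_NAMES]
    keep = ~feats.isna().any(axis=1)
    kept = observations.loc[keep].reset_index(drop=True).copy()
    report = (
        pd.DataFrame({
            "participant_id": observations["participant_id"],
            "kept": keep.astype(int),
        })
        .groupby("participant_id", as_index=False)
        .agg(n_total=("kept", "size"), n_kept=("kept", "sum"))
    )
    kept["label"] = binarize_absolute(kept["response"])
    return LabeledDataset(observations=kept, variant=variant,
                          labeling="absolute", removal_report=report)


def participant_statistics(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean/SD (population) of features and mean response."""
    g = observations.groupby("participant_id")
    means = g[FEATURE_NAMES].mean()
    sds = g[FEATURE_NAMES].std(ddof=0).fillna(0.0)
    head = pd.DataFrame({"participant_id": means.index,
                         "n": g.size().to_numpy(),
                         "response_mean": g["response"].mean().to_numpy()})
    means = means.add_suffix("__mean").reset_index(drop=True)
    sds = sds.add_suffix("__sd").reset_index(drop=True)
    return pd.concat([head, means, sds], axis=1)


def apply_normalization(observations: pd.DataFrame,
                        stats: pd.DataFrame) -> pd.DataFrame:
    """Z-score features and relabel against the personal mean response.

    A feature with zero within-participant SD maps to 0 (the observation is
    kept).  The label is high iff the raw response is at least the
    participant's mean response.
    """
    out = observations.copy()
    s = stats.set_index("participant_id")
    pid = observations["participant_id"]
    M = s.loc[pid, [f"{f}__mean" for f in FEATURE_NAMES]].to_numpy(dtype=float)
    SD = s.loc[pid, [f"{f}__sd" for f in FEATURE_NAMES]].to_numpy(dtype=float)
    X = observations[FEATURE_NAMES].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(SD > 0, (X - M) / np.where(SD > 0, SD, 1.0), 0.0)
    out[FEATURE_NAMES] = Z
    rm = s.loc[pid, "response_mean"].to_numpy(dtype=float)
    out["label"] = (observations["response"].to_numpy(dtype=float) >= rm).astype(int)
    return out


def normalize_per_participant(dataset: LabeledDataset) -> LabeledDataset:
    """Per-participant normalization of features and response labels.

    Participants with fewer than 2 observations or fewer than 2 unique
    responses cannot be normalized and are excluded with a warning.
    """
    obs = dataset.observations
    eligible = []
    for pid, grp in obs.groupby("participant_id"):
        if len(grp) >= 2 and grp["response"].nunique() >= 2:
            eligible.append(pid)
        else:
            warnings.warn(
                f"participant {pid} excluded from normalization: needs >= 2 "
                f"observations with >= 2 unique responses", stacklevel=2)
    obs = obs[obs["participant_id"].isin(eligible)].reset_index(drop=True)
    stats = participant_statistics(obs)
    normalized = apply_normalization(obs, stats)
    return LabeledDataset(observations=normalized, variant=dataset.variant,
                          labeling="normalized", participant_stats=stats,
                          removal_report=dataset.removal_report)


def label_balance_report(observations: pd.DataFrame,
                         scheme: str = "population_cutoff") -> pd.DataFrame:
    """Proportion of the under-represented binary label per participant.

    ``population_cutoff`` thresholds at response >= 4 for everyone;
    ``personal_mean`` at each participant's own mean response.  Proportions
    lie in [0, 0.5] by construction.
    """
    if scheme not in ("population_cutoff", "personal_mean"):
        raise ValidationError(f"unknown labeling scheme {scheme!r}")
    rows = []
    for pid, grp in observations.groupby("participant_id"):
        r = grp["response"].to_numpy()
        if scheme == "population_cutoff":
            high = r >= 4
        else:
            high = r >= r.mean()
        p_high = float(np.mean(high))
        rows.append({"participant_id": pid, "n": len(grp),
                     "underrepresented_prop": min(p_high, 1.0 - p_high)})
    return pd.DataFrame(rows)


def variance_decomposition(observations: pd.DataFrame) -> pd.DataFrame:
    """Between- vs within-participant variation per feature.

    between_sd is the SD of the per-participant mean values; within_sd is
    the mean of the per-participant SDs (population convention).
    """
    rows = []
    grouped = observations.groupby("participant_id")
    for f in FEATURE_NAMES:
        if f not in observations.columns:
            continue
        means = grouped[f].mean()
        sds = grouped[f].apply(lambda v: float(np.std(v.to_numpy())))
        rows.append({"feature": f, "group": FEATURE_GROUPS[f],
                     "between_sd": float(np.std(means.to_numpy())),
                     "within_sd": float(np.mean(sds.to_numpy()))})
    return pd.DataFrame(rows)
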