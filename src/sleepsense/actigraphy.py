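"""Activity counts, Sadeh / Cole-Kripke sleep-wake scoring and sleep periods.

Wrist acceleration is condensed into one activity count per 60-second epoch:
each axis is high-passed at 0.25 Hz (removing gravity and posture), the
maximum absolute filtered deviation across axes is taken per second, and the
per-second values are summed over the epoch and scaled by 100.  Two published
linear scoring rules then classify each epoch as sleep or wake:

* Sadeh: ``PS = 7.601 - 0.065*MW5 - 1.08*NAT - 0.056*SD6 - 0.703*LG`` with
  MW5 the mean count in the centered 11-epoch window, NAT the number of
  epochs in that window with counts in [50, 100), SD6 the standard deviation
  of the current and previous 5 epochs, and LG the natural log of the current
  count + 1.  ``PS >= 0`` scores sleep.
* Cole-Kripke (1-minute epochs): ``D = 0.001 * (106 A[-4] + 54 A[-3] +
  58 A[-2] + 76 A[-1] + 230 A[0] + 74 A[+1] + 67 A[+2])``; ``D < 1`` scores
  sleep.

Sleep onset is the start of the first run of >= 10 consecutive sleep-scored
epochs at or after the reported bedtime; wake is the end of the last such run
ending within +-30 minutes of the reported wake time.  The final onset and
wake are the arithmetic means of the two algorithms' estimates.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional

import numpy as np
from scipy import signal as _sig

from .signal_io import ChannelRecording, DiaryEntry, ValidationError

__all__ = [
    "ActivityCounts",
    "SleepWakeSeries",
    "SleepPeriod",
    "SleepPeriodMissing",
    "activity_counts",
    "sadeh_score",
    "cole_kripke_score",
    "score_sleep_wake",
    "estimate_sleep_period",
    "actigraphy_features",
    "EPOCH_S",
]

EPOCH_S = 60.0

SADEH_INTERCEPT = 7.601
SADEH_MEAN_W = 0.065
SADEH_NAT_W = 1.08
SADEH_SD_W = 0.056
SADEH_LOG_W = 0.703

COLE_KRIPKE_P = 0.001
COLE_KRIPKE_WEIGHTS = np.array([106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0])
COLE_KRIPKE_CENTER = 4  # index of A[0] in the weight vector

ONSET_RUN_EPOCHS = 10      # >= 10 consecutive sleep epochs define onset/wake runs
WAKE_SEARCH_S = 1800.0     # one-hour window around reported wake: +-30 min


class SleepPeriodMissing(ValueError):
    """No qualifying sleep onset/wake could be estimated for the night."""


@dataclasses.dataclass
class ActivityCounts:
    """Non-negative activity counts on a 60-second epoch grid."""

    epoch_starts: np.ndarray  # absolute UTC seconds
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.epoch_starts) != len(self.counts):
            raise ValidationError("epoch grid and counts must align")
        if np.any(self.counts < 0):
            raise ValidationError("activity counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


@dataclasses.dataclass
class SleepWakeSeries:
    """Per-epoch scores and binary states for both scoring algorithms."""

    epoch_starts: np.ndarray
    sadeh_score: np.ndarray
    sadeh_asleep: np.ndarray
    cole_kripke_score: np.ndarray
    cole_kripke_asleep: np.ndarray


@dataclasses.dataclass
class SleepPeriod:
    """Estimated sleep window for one night, anchored to the diary."""

    onset: float
    wake: float
    latency_min: float
    duration_min: float

    def __post_init__(self) -> None:
        if self.latency_min < 0:
            raise ValidationError("sleep latency cannot be negative")
        if self.duration_min <= 0:
            raise ValidationError("sleep duration must be positive")


def activity_counts(acc: ChannelRecording, highpass_hz: float = 0.25,
                    epoch_s: float = EPOCH_S) -> ActivityCounts:
    """Activity counts per 60-second epoch from the 3-axis accelerometer.

    Per-axis 4th-order Butterworth high-pass at 0.25 Hz removes gravity; the
    per-second value is the maximum absolute filtered deviation across axes
    (g); the epoch count is the floored sum of per-second values times 100.
    """
    if acc.channel != "ACC":
        raise ValidationError(f"activity_counts expects an ACC channel, got {acc.channel}")
    fs = acc.fs
    sos = _sig.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    filtered = _sig.sosfiltfilt(sos, acc.samples, axis=0)
    per_sample = np.max(np.abs(filtered), axis=1)
    spb = int(round(fs))  # samples per second
    n_seconds = len(per_sample) // spb
    per_second = per_sample[: n_seconds * spb].reshape(n_seconds, spb).max(axis=1)
    epochs = int(n_seconds // epoch_s)
    secs_per_epoch = int(epoch_s)
    counts = np.floor(
        per_second[: epochs * secs_per_epoch]
        .reshape(epochs, secs_per_epoch)
        .sum(axis=1) * 100.0
    )
    starts = acc.start_time + np.arange(epochs) * epoch_s
    return ActivityCounts(epoch_starts=starts, counts=counts)


def sadeh_score(counts: ActivityCounts) -> tuple[np.ndarray, np.ndarray]:
    """Sadeh sleep score PS per epoch; PS >= 0 scores sleep.

    Boundary epochs use truncated windows.
    """
    a = counts.counts
    n = len(a)
    ps = np.empty(n)
    for i in range(n):
        w = a[max(0, i - 5): i + 6]
        mw5 = np.mean(w)
        nat = np.sum((w >= 50) & (w < 100))
        trail = a[max(0, i - 5): i + 1]
        sd6 = np.std(trail, ddof=0)
        lg = np.log(a[i] + 1.0)
        ps[i] = (SADEH_INTERCEPT - SADEH_MEAN_W * mw5 - SADEH_NAT_W * nat
                 - SADEH_SD_W * sd6 - SADEH_LOG_W * lg)
    return ps, ps >= 0


def cole_kripke_score(counts: ActivityCounts) -> tuple[np.ndarray, np.ndarray]:
    """Cole-Kripke weighted sum D per epoch; D < 1 scores sleep.

    Boundary epochs treat out-of-range neighbors as zero activity.
    """
    a = counts.counts
    n = len(a)
    d = np.zeros(n)
    for k, w in enumerate(COLE_KRIPKE_WEIGHTS):
        offset = k - COLE_KRIPKE_CENTER  # -4 .. +2
        shifted = np.zeros(n)
        if offset < 0:
            shifted[-offset:] = a[:n + offset]
        elif offset > 0:
            shifted[:n - offset] = a[offset:]
        else:
            shifted = a.astype(float)
        d += w * shifted
    d *= COLE_KRIPKE_P
    return d, d < 1.0


def score_sleep_wake(counts: ActivityCounts) -> SleepWakeSeries:
    """Run both scoring algorithms over one count series."""
    s_score, s_state = sadeh_score(counts)
    c_score, c_state = cole_kripke_score(counts)
    return SleepWakeSeries(
        epoch_starts=counts.epoch_starts,
        sadeh_score=s_score,
        sadeh_asleep=s_state,
        cole_kripke_score=c_score,
        cole_kripke_asleep=c_state,
    )


def _runs(asleep: np.ndarray):
    """(start_idx, end_idx_exclusive) of maximal consecutive sleep runs."""
    out = []
    i = 0
    n = len(asleep)
    while i < n:
        if asleep[i]:
            j = i
            while j < n and asleep[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _onset_wake_for(asleep: np.ndarray, starts: np.ndarray, diary: DiaryEntry,
                    epoch_s: float):
    runs = [(i, j) for i, j in _runs(asleep) if j - i >= ONSET_RUN_EPOCHS]
    onset = None
    for i, j in runs:
        t = starts[i]
        if t >= diary.reported_bedtime - 1e-9:
            onset = t
            break
    if onset is None:
        raise SleepPeriodMissing(
            f"{diary.participant_id}/{diary.night_date}: no 10-minute sleep "
            f"run found after the reported bedtime"
        )
    wake = None
    for i, j in runs:
        end = starts[j - 1] + epoch_s
        if abs(end - diary.reported_waketime) <= WAKE_SEARCH_S and end > onset:
            wake = end  # last qualifying run wins
    if wake is None:
        raise SleepPeriodMissing(
            f"{diary.participant_id}/{diary.night_date}: no 10-minute sleep "
            f"run ends within 30 minutes of the reported wake time"
        )
    return onset, wake


def estimate_sleep_period(series: SleepWakeSeries, diary: DiaryEntry,
                          epoch_s: float = EPOCH_S) -> SleepPeriod:
    """Diary-anchored sleep period averaged over both scoring algorithms."""
    s_onset, s_wake = _onset_wake_for(series.sadeh_asleep, series.epoch_starts,
                                      diary, epoch_s)
    c_onset, c_wake = _onset_wake_for(series.cole_kripke_asleep,
                                      series.epoch_starts, diary, epoch_s)
    onset = (s_onset + c_onset) / 2.0
    wake = (s_wake + c_wake) / 2.0
    return SleepPeriod(
        onset=onset,
        wake=wake,
        latency_min=max(0.0, (onset - diary.reported_bedtime) / 60.0),
        duration_min=(wake - onset) / 60.0,
    )


def actigraphy_features(counts: ActivityCounts, sleep_period: SleepPeriod,
                        awake_window=None) -> Dict[str, float]:
    """The 4 actigraphy features for one night."""
    from .signal_io import phase_masks

    mids = counts.epoch_starts + EPOCH_S / 2.0
    awake, asleep = phase_masks(mids, sleep_period.onset, sleep_period.wake,
                                awake_window)
    return {
        "sleep_duration_min": float(sleep_period.duration_min),
        "sleep_onset_latency_min": float(sleep_period.latency_min),
        "counts_awake_sum": float(np.sum(counts.counts[awake])),
        "counts_asleep_sum": float(np.sum(counts.counts[asleep])),
    }
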