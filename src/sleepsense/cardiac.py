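"""Heart rate and heart-rate-variability features from device IBIs or raw BVP.

Two conditions are supported, mirroring how wrist wearables expose cardiac
data: *device* — the watch's own inter-beat intervals, which already have
motion-artifact segments removed and therefore contain discontinuities — and
*processed* — beats detected by this module from the band-passed blood volume
pulse.  Both feed the same 5-minute windowing (2.5-minute overlap) and the
same time-domain metrics: HR, RMSSD, SDNN and the Poincare long axis SD2.
Windows with missing or low-quality beats are dropped, never interpolated.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy.ndimage import uniform_filter1d

from .signal_io import ChannelRecording, ValidationError

__all__ = [
    "IBISeries",
    "CardiacWindow",
    "AdjustmentReference",
    "bandpass_bvp",
    "detect_beats",
    "window_ibis",
    "hrv_metrics",
    "adjust_hrv",
    "aggregate_cardiac",
    "CARDIAC_METRICS",
    "WINDOW_S",
    "STEP_S",
    "COVERAGE_FRAC",
]

CARDIAC_METRICS = ("hr", "rmssd", "sdnn", "sd2")

#: Analysis window length and step (5 min / 2.5-min overlap).
WINDOW_S = 300.0
STEP_S = 150.0

#: A window is kept only when its IBIs cover at least this fraction of it.
COVERAGE_FRAC = 0.95

#: Physiologically plausible single-IBI range (ms).
IBI_PLAUSIBLE_MS = (300.0, 2000.0)

#: Quality gate for processed windows: reject when more than 10% of beats are
#: rhythm outliers or more than 5% of IBIs are implausible.
MAX_REJECTED_FRAC = 0.10
MAX_IMPLAUSIBLE_FRAC = 0.05


@dataclasses.dataclass
class IBISeries:
    """Timestamped inter-beat intervals with validity flags.

    ``ibis[i]`` (ms) is the interval ending at ``beat_times[i]`` (s).
    ``contiguous[i]`` is True when beat ``i`` directly follows beat ``i-1``
    with no dropped segment in between.
    """

    beat_times: np.ndarray
    ibis: np.ndarray
    valid: np.ndarray
    contiguous: np.ndarray
    source: str = "device"
    rejected: Optional[np.ndarray] = None
    implausible: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.contiguous = np.asarray(self.contiguous, dtype=bool)
        n = len(self.beat_times)
        if not (len(self.ibis) == len(self.valid) == len(self.contiguous) == n):
            raise ValidationError("IBISeries arrays must have equal length")
        if n > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValidationError("beat times must be strictly increasing")
        if self.source not in ("device", "processed"):
            raise ValidationError(f"unknown IBI source {self.source!r}")

    def __len__(self) -> int:
        return len(self.beat_times)


@dataclasses.dataclass
class CardiacWindow:
    """Per-window HR/HRV metrics with the window-retention flag."""

    start: float
    duration: float
    hr: float
    rmssd: float
    sdnn: float
    sd2: float
    n_beats: int
    quality_ok: bool


def bandpass_bvp(raw: ChannelRecording, lowcut: float = 0.5, highcut: float = 10.0,
                 order: int = 4, rs_db: float = 20.0) -> ChannelRecording:
    """Band-pass the raw BVP with a 4th-order Chebyshev type II filter.

    Cutoffs 0.5-10 Hz retain the pulse fundamental and its first harmonics
    while removing baseline drift and high-frequency noise.  Chebyshev II
    filters are parameterized by their stopband edges; these are placed at
    half the lower and 1.3x the upper cutoff so that the pulse band (around
    1-2 Hz) passes essentially unattenuated while drift (< 0.05 Hz) and
    high-frequency noise (> 25 Hz) are suppressed by more than 20 dB.  The
    filter is applied forward-backward (zero phase) so systolic peak timing
    is preserved.
    """
    if raw.channel != "BVP":
        raise ValidationError(f"bandpass_bvp expects a BVP channel, got {raw.channel}")
    if raw.fs <= 2 * highcut:
        raise ValidationError(
            f"sampling rate {raw.fs} Hz cannot realize a {highcut} Hz upper cutoff"
        )
    stop_edges = [0.5 * lowcut, min(1.3 * highcut, 0.49 * raw.fs)]
    sos = _sig.cheby2(order // 2, rs_db, stop_edges, btype="bandpass",
                      fs=raw.fs, output="sos")
    # the stopband floor of a Chebyshev II is equiripple, not zero; remove
    # the (arbitrary-unit) DC offset exactly before filtering
    filtered = _sig.sosfiltfilt(sos, raw.samples - np.mean(raw.samples))
    return ChannelRecording(channel="BVP", start_time=raw.start_time, fs=raw.fs,
                            samples=filtered)


def _refine_peak(x: np.ndarray, idx: int) -> float:
    """Sub-sample peak position by parabolic interpolation of 3 points."""
    if idx <= 0 or idx >= len(x) - 1:
        return float(idx)
    y0, y1, y2 = x[idx - 1], x[idx], x[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(idx)
    delta = 0.5 * (y0 - y2) / denom
    return float(idx) + float(np.clip(delta, -0.5, 0.5))


def detect_beats(filtered: ChannelRecording, rolling_s: float = 0.75,
                 refractory_s: float = 0.3, outlier_frac: float = 0.3) -> IBISeries:
    """Detect systolic peaks in band-passed BVP by adaptive thresholding.

    Candidate beats are local maxima above a rolling-mean threshold
    (window ``rolling_s``); peaks closer than the ``refractory_s`` refractory
    period to the previous accepted beat are discarded.  Each resulting IBI
    is flagged *rejected* when it deviates from the local median rhythm by
    more than ``outlier_frac``, and *implausible* when outside 300-2000 ms.
    Those flags drive the per-window quality gate in :func:`window_ibis`.
    """
    x = np.asarray(filtered.samples, dtype=float)
    fs = filtered.fs
    if np.ptp(x) == 0:
        empty = np.empty(0)
        return IBISeries(empty, empty, np.empty(0, bool), np.empty(0, bool),
                         source="processed",
                         rejected=np.empty(0, bool), implausible=np.empty(0, bool))
    win = max(int(round(rolling_s * fs)), 1)
    baseline = uniform_filter1d(x, size=win, mode="nearest")
    # raise the threshold above the rolling mean by a robust amplitude term
    mad = np.median(np.abs(x - np.median(x)))
    thr = baseline + 0.5 * mad
    above = x > thr
    idx = np.flatnonzero(above)
    if idx.size == 0:
        empty = np.empty(0)
        return IBISeries(empty, empty, np.empty(0, bool), np.empty(0, bool),
                         source="processed",
                         rejected=np.empty(0, bool), implausible=np.empty(0, bool))
    breaks = np.flatnonzero(np.diff(idx) > 1)
    seg_starts = np.concatenate(([0], breaks + 1))
    seg_ends = np.concatenate((breaks, [idx.size - 1]))
    peaks = []
    for s, e in zip(seg_starts, seg_ends):
        seg = idx[s:e + 1]
        peaks.append(seg[np.argmax(x[seg])])
    # refractory pruning: keep the larger peak of any pair closer than refractory
    refractory = refractory_s * fs
    kept: List[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refractory:
            if x[p] > x[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    if len(kept) < 2:
        empty = np.empty(0)
        return IBISeries(empty, empty, np.empty(0, bool), np.empty(0, bool),
                         source="processed",
                         rejected=np.empty(0, bool), implausible=np.empty(0, bool))
    pos = np.asarray([_refine_peak(x, p) for p in kept])
    beat_times = filtered.start_time + pos / fs
    ibis = np.diff(beat_times) * 1000.0
    beat_times = beat_times[1:]
    n = len(ibis)
    implausible = (ibis < IBI_PLAUSIBLE_MS[0]) | (ibis > IBI_PLAUSIBLE_MS[1])
    # rhythm outliers vs the local median IBI (11-beat centered window)
    med = pd.Series(ibis).rolling(11, center=True, min_periods=1).median().to_numpy()
    rejected = np.abs(ibis - med) > outlier_frac * med
    valid = ~(implausible | rejected)
    contiguous = np.ones(n, dtype=bool)
    contiguous[0] = False
    return IBISeries(beat_times, ibis, valid, contiguous, source="processed",
                     rejected=rejected, implausible=implausible)


def hrv_metrics(ibis_ms: np.ndarray) -> Dict[str, float]:
    """Time-domain metrics of one window of inter-beat intervals.

    HR = 60000 / mean(IBI); RMSSD = sqrt(mean(diff^2)); SDNN = population SD
    of the IBIs; SD2 = sqrt(max(0, 2*SDNN^2 - SDSD^2/2)) with SDSD the
    population SD of successive differences (Poincare plot long axis).
    """
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    if len(ibis_ms) < 3:
        raise ValidationError("hrv_metrics requires at least 3 IBIs")
    if np.any(ibis_ms <= 0):
        raise ValidationError("IBIs must be positive")
    diffs = np.diff(ibis_ms)
    sdnn = float(np.std(ibis_ms))
    sdsd = float(np.std(diffs))
    return {
        "hr": 60000.0 / float(np.mean(ibis_ms)),
        "rmssd": float(np.sqrt(np.mean(diffs ** 2))),
        "sdnn": sdnn,
        "sd2": float(np.sqrt(max(0.0, 2.0 * sdnn ** 2 - 0.5 * sdsd ** 2))),
    }


def window_ibis(ibis: IBISeries, mode: Optional[str] = None,
                window_s: float = WINDOW_S, step_s: float = STEP_S,
                coverage_frac: float = COVERAGE_FRAC,
                t0: Optional[float] = None,
                t_end: Optional[float] = None) -> List[CardiacWindow]:
    """Cut an IBI series into 5-minute windows stepped by 2.5 minutes.

    Device mode keeps a window only when every beat in it is contiguous
    (no device-dropped segment) and valid; processed mode applies the
    detector's quality gate.  Both require the summed IBIs to cover at least
    ``coverage_frac`` of the window.  Metrics are computed on kept windows
    only and never interpolated.
    """
    if mode is None:
        mode = ibis.source
    if len(ibis) == 0:
        return []
    if t0 is None:
        t0 = float(ibis.beat_times[0] - ibis.ibis[0] / 1000.0)
    if t_end is None:
        t_end = float(ibis.beat_times[-1])
    windows: List[CardiacWindow] = []
    start = t0
    times = ibis.beat_times
    while start + window_s <= t_end + 1e-9:
        lo = np.searchsorted(times, start, side="left")
        hi = np.searchsorted(times, start + window_s, side="left")
        w_ibis = ibis.ibis[lo:hi]
        n = hi - lo
        ok = n >= 3
        if ok:
            coverage = np.sum(w_ibis) / 1000.0 >= coverage_frac * window_s
            if mode == "device":
                # all beats after the first must be contiguous, all valid
                gate = bool(np.all(ibis.contiguous[lo + 1:hi]) and np.all(ibis.valid[lo:hi]))
            else:
                rej = ibis.rejected[lo:hi] if ibis.rejected is not None else ~ibis.valid[lo:hi]
                imp = ibis.implausible[lo:hi] if ibis.implausible is not None else np.zeros(n, bool)
                gate = (np.mean(rej) <= MAX_REJECTED_FRAC
                        and np.mean(imp) <= MAX_IMPLAUSIBLE_FRAC)
            ok = bool(coverage and gate)
        if ok:
            m = hrv_metrics(w_ibis)
            windows.append(CardiacWindow(start=start, duration=window_s,
                                         hr=m["hr"], rmssd=m["rmssd"],
                                         sdnn=m["sdnn"], sd2=m["sd2"],
                                         n_beats=int(n), quality_ok=True))
        else:
            windows.append(CardiacWindow(start=start, duration=window_s,
                                         hr=np.nan, rmssd=np.nan, sdnn=np.nan,
                                         sd2=np.nan, n_beats=int(n),
                                         quality_ok=False))
        start += step_s
    return windows


class AdjustmentReference:
    """Stratified reference for adjusting HRV metrics.

    HRV differs systematically with gender, age and time of day, which makes
    raw values hard to compare across windows.  The reference stores the mean
    and SD of each metric within gender x age-decade x 3-hour-of-day strata
    estimated from training windows; adjustment is the stratum z-score.
    Strata with fewer than ``min_stratum`` windows fall back to the pooled
    statistics.
    """

    ADJUSTED = ("rmssd", "sdnn", "sd2")

    def __init__(self, min_stratum: int = 10):
        self.min_stratum = min_stratum
        self._strata: Dict[tuple, Dict[str, tuple]] = {}
        self._pooled: Dict[str, tuple] = {}

    @staticmethod
    def stratum_key(gender: str, age: float, window_start: float) -> tuple:
        hour = (window_start % 86400.0) / 3600.0
        return (str(gender), int(age // 10), int(hour // 3))

    def fit(self, window_table: pd.DataFrame) -> "AdjustmentReference":
        """Fit from a table with columns gender, age, start and the metrics."""
        if len(window_table) == 0:
            raise ValidationError("cannot fit an adjustment reference on no windows")
        df = window_table.dropna(subset=list(self.ADJUSTED))
        if len(df) == 0:
            raise ValidationError("no complete windows to fit the reference on")
        keys = [self.stratum_key(g, a, s)
                for g, a, s in zip(df["gender"], df["age"], df["start"])]
        df = df.assign(_key=keys)
        for metric in self.ADJUSTED:
            sd = float(np.std(df[metric]))
            self._pooled[metric] = (float(np.mean(df[metric])), sd if sd > 0 else 1.0)
        for key, grp in df.groupby("_key"):
            if len(grp) < self.min_stratum:
                continue
            self._strata[key] = {}
            for metric in self.ADJUSTED:
                sd = float(np.std(grp[metric]))
                self._strata[key][metric] = (float(np.mean(grp[metric])),
                                             sd if sd > 0 else 1.0)
        return self

    def adjust(self, value: float, metric: str, gender: str, age: float,
               window_start: float) -> float:
        if not self._pooled:
            raise ValidationError("adjustment reference is empty (not fitted)")
        key = self.stratum_key(gender, age, window_start)
        mean, sd = self._strata.get(key, {}).get(metric, self._pooled[metric])
        return (value - mean) / sd


def adjust_hrv(windows: List[CardiacWindow], age: float, gender: str,
               reference: AdjustmentReference) -> List[CardiacWindow]:
    """Return windows with RMSSD/SDNN/SD2 replaced by stratum z-scores.

    HR is left raw: the adjustment targets HRV metrics only.
    """
    out = []
    for w in windows:
        if not w.quality_ok:
            out.append(w)
            continue
        out.append(dataclasses.replace(
            w,
            rmssd=reference.adjust(w.rmssd, "rmssd", gender, age, w.start),
            sdnn=reference.adjust(w.sdnn, "sdnn", gender, age, w.start),
            sd2=reference.adjust(w.sd2, "sd2", gender, age, w.start),
        ))
    return out


def aggregate_cardiac(windows: List[CardiacWindow], sleep_period,
                      awake_window=None) -> Dict[str, float]:
    """Collapse kept windows into the 24 cardiac features.

    Windows are assigned awake/asleep by their midpoint falling inside the
    half-open sleep period ``[onset, wake)``; awake windows may further be
    restricted to ``awake_window``.  A phase with no kept windows yields NaN
    (missing) for its 12 slots.
    """
    from .signal_io import phase_masks

    features: Dict[str, float] = {}
    kept = [w for w in windows if w.quality_ok]
    mids = np.asarray([w.start + w.duration / 2.0 for w in kept])
    awake_mask, asleep_mask = phase_masks(mids, sleep_period.onset,
                                          sleep_period.wake, awake_window)
    for phase, mask in (("awake", awake_mask), ("asleep", asleep_mask)):
        phase_windows = [w for w, m in zip(kept, mask) if m]
        for metric in CARDIAC_METRICS:
            vals = np.asarray([getattr(w, metric) for w in phase_windows])
            for stat, fn in (("mean", np.mean), ("max", np.max), ("min", np.min)):
                name = f"{metric}_{stat}_{phase}"
                features[name] = float(fn(vals)) if len(vals) else float("nan")
    return features
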