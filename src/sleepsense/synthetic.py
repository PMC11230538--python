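"""Synthetic wearable cohorts with planted ground truth.

Every downstream stage of the pipeline is testable by recovery: the
generator plants the quantity a stage is supposed to estimate (beat times,
EDA artifact blocks, sleep onset/wake, label-model coefficients) and returns
it alongside the rendered signals.

Two levels of fidelity are provided:

* **Signal level** (:func:`simulate_cohort` / :func:`iter_cohort`): full
  multi-channel sessions in the device's native rates — pulse-train BVP with
  planted inter-beat intervals, EDA with baseline drift plus planted
  artifact segments of all three rule-violating kinds, rest/active
  accelerometer epochs bracketing the planted sleep period, and a
  circadian-shaped skin temperature.  A device-style IBI series is derived
  from the planted beats with motion-artifact segments removed.
* **Feature level** (:func:`simulate_observations`): per-night 52-feature
  vectors drawn from a participant-random-effects model, with Likert
  responses from a planted logistic-style latent model.  This is the scale
  at which the modeling and interpretation stages are exercised.

Determinism: every stream is derived from ``(seed, participant, night)`` so
cohorts are reproducible and compose participant-wise.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import zlib
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import eda as _eda
from .actigraphy import EPOCH_S
from .signal_io import (ChannelRecording, DiaryEntry, RecordingSession,
                        ValidationError)

__all__ = [
    "CohortSpec",
    "NightGroundTruth",
    "simulate_cohort",
    "iter_cohort",
    "simulate_bvp",
    "simulate_eda",
    "simulate_acc",
    "simulate_temp",
    "simulate_observations",
    "generate_labels",
    "participant_rng",
]

_EPOCH_ANCHOR = 1704067200.0  # 2024-01-01T00:00:00Z
_BASE_DATE = _dt.date(2024, 1, 1)


@dataclasses.dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate the study protocol this package targets: 16
    participants wearing the device for 30 nights, ages 19-35, putting the
    watch on four hours before bed and keeping it for four hours after
    waking.
    """

    n_participants: int = 16
    n_nights: int = 30
    seed: int = 0
    #: which channels to render at signal level
    channels: Tuple[str, ...] = ("BVP", "EDA", "ACC", "TEMP")
    #: sleep architecture (hours / minutes)
    mean_sleep_h: float = 7.2
    between_sleep_sd_h: float = 0.5
    within_sleep_sd_h: float = 0.75
    mean_latency_min: float = 12.0
    wear_margin_h: float = 4.0
    #: cardiac conditions
    bvp_snr_db: float = 10.0
    #: device IBI dropout (motion-artifact segments removed by the watch)
    device_artifact_per_h_awake: float = 10.0
    device_artifact_per_h_asleep: float = 1.5
    device_artifact_dur_s: Tuple[float, float] = (60.0, 400.0)
    #: EDA artifact rates (planted segments per night, per kind)
    eda_artifacts_per_night: float = 3.0
    #: label model
    label_coeffs: Optional[Dict[str, float]] = None
    label_noise_sd: float = 0.5
    intercept_sd: float = 0.5
    likert_cuts: Tuple[float, float, float, float] = (0.10, 0.30, 0.65, 0.90)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("a cohort needs at least 2 participants")
        if self.n_nights < 2:
            raise ValidationError(
                "per-participant normalization needs at least 2 nights"
            )
        if self.label_coeffs is None:
            self.label_coeffs = {"sleep_duration_min": 1.0, "hr_mean_awake": -1.0}

    def participant_ids(self) -> List[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_participants)]


@dataclasses.dataclass
class NightGroundTruth:
    """Everything planted for one night."""

    participant_id: str
    night_date: _dt.date
    session_start: float
    session_end: float
    bedtime: float
    onset: float
    wake: float
    reported_waketime: float
    beat_times: np.ndarray          # absolute s, one per planted beat
    ibis_ms: np.ndarray
    device_dropped: np.ndarray      # True where the device masked the beat
    eda_block_rule: Optional[np.ndarray]  # per-1s-block rule code (eda.RULE_*)
    planted_features: Dict[str, float]
    latent: float = float("nan")
    response: int = 0

    @property
    def duration_min(self) -> float:
        return (self.wake - self.onset) / 60.0

    @property
    def latency_min(self) -> float:
        return (self.onset - self.bedtime) / 60.0


def participant_rng(seed: int, participant_id: str, *extra: int) -> np.random.Generator:
    """Independent, reproducible stream per (seed, participant, ...)."""
    crc = zlib.crc32(participant_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, crc, *[int(e) for e in extra]])


# ---------------------------------------------------------------------------
# Channel simulators
# ---------------------------------------------------------------------------

def _pulse_template(fs: float) -> np.ndarray:
    """One PPG-like pulse: systolic peak plus a dicrotic bump."""
    t = np.arange(int(round(0.7 * fs))) / fs
    systolic = np.exp(-0.5 * ((t - 0.12) / 0.045) ** 2)
    dicrotic = 0.35 * np.exp(-0.5 * ((t - 0.38) / 0.07) ** 2)
    return systolic + dicrotic


def simulate_bvp(ibis_ms: Sequence[float], fs: float = 64.0,
                 snr_db: float = 10.0, rng: Optional[np.random.Generator] = None,
                 start_time: float = 0.0) -> ChannelRecording:
    """Render a pulse-train BVP from planted inter-beat intervals.

    One pulse template is placed per beat; Gaussian noise is added at the
    requested SNR (in dB, relative to the RMS of the clean train).  Beat
    recovery by the detector is feasible down to roughly 10 dB.
    """
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    if len(ibis_ms) == 0:
        raise ValidationError("cannot render BVP from an empty IBI list")
    if np.any(ibis_ms <= 0):
        raise ValidationError("planted IBIs must be positive")
    rng = rng or np.random.default_rng(0)
    beat_offsets = np.cumsum(ibis_ms) / 1000.0
    template = _pulse_template(fs)
    n = int(np.ceil((beat_offsets[-1] + 1.0) * fs))
    x = np.zeros(n)
    # systolic peak of the template sits at 0.12 s; align it to the beat time
    peak_shift = int(round(0.12 * fs))
    starts = np.rint(beat_offsets * fs).astype(int) - peak_shift
    tlen = len(template)
    for s in starts:
        lo = max(s, 0)
        hi = min(s + tlen, n)
        if hi > lo:
            x[lo:hi] += template[lo - s: hi - s]
    rms = float(np.sqrt(np.mean(x ** 2)))
    noise_sd = rms * 10 ** (-snr_db / 20.0)
    x = x + rng.normal(0.0, noise_sd, size=n)
    return ChannelRecording(channel="BVP", start_time=start_time, fs=fs, samples=x)


def _eda_background(n: int, fs: float, level: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Drifting tonic level with a deterministic per-second ripple.

    The ripple (0.03 uS on alternate samples) guarantees every 1-second
    block changes by more than the flatline threshold; the drift slope is
    bounded far inside the physiological +-(20%/10%) per-second band.
    """
    t = np.arange(n) / fs
    drift = 0.3 * np.sin(2 * np.pi * t / 5400.0 + rng.uniform(0, 2 * np.pi))
    slow = 0.15 * np.sin(2 * np.pi * t / 14400.0 + rng.uniform(0, 2 * np.pi))
    ripple = np.where(np.arange(n) % 2 == 1, 0.03, 0.0)
    noise = rng.normal(0.0, 0.002, size=n)
    return level + drift + slow + ripple + noise


def simulate_eda(gt: NightGroundTruth, rng: np.random.Generator,
                 fs: float = 4.0, level: Optional[float] = None,
                 artifacts_per_night: float = 3.0) -> Tuple[ChannelRecording, np.ndarray]:
    """EDA channel with planted artifact segments of all three kinds.

    Returns the recording and the planted per-1-second-block rule-code mask
    (0 = valid).  Segment boundaries are placed so that the mask is exactly
    what the validation rules recover: a low-contact segment additionally
    invalidates its preceding block (the >10%/s drop into the segment), a
    frozen (flatline) segment resumes near the frozen value, and a rate
    spike decays at under 10% per second.
    """
    n = int(round((gt.session_end - gt.session_start) * fs))
    block = int(round(fs))
    n_blocks = n // block
    if level is None:
        level = float(rng.uniform(1.5, 4.0))
    x = _eda_background(n, fs, level, rng)
    planted = np.zeros(n_blocks, dtype=int)

    n_each = rng.poisson(artifacts_per_night) if artifacts_per_night > 0 else 0
    kinds = (["low"] * n_each + ["flat"] * n_each + ["rate"] * n_each)
    # disjoint placement on the block grid, away from the edges
    occupied = np.zeros(n_blocks, dtype=bool)
    occupied[:4] = occupied[-8:] = True
    for kind in kinds:
        dur_blocks = int(rng.integers(20, 90)) if kind != "rate" else 4
        for _attempt in range(50):
            a = int(rng.integers(4, max(5, n_blocks - dur_blocks - 8)))
            if not occupied[a - 3: a + dur_blocks + 4].any():
                break
        else:
            continue
        occupied[a - 3: a + dur_blocks + 4] = True
        sl = slice(a * block, (a + dur_blocks) * block)
        if kind == "low":
            seg_n = (a + dur_blocks) * block - a * block
            low_ripple = np.where(np.arange(seg_n) % 2 == 1, 0.005, 0.0)
            x[sl] = 0.02 + low_ripple
            planted[a: a + dur_blocks] = _eda.RULE_LOW_AMPLITUDE
            planted[a - 1] = _eda.RULE_RATE  # the drop into the segment
        elif kind == "flat":
            x[sl] = x[a * block]
            planted[a: a + dur_blocks] = _eda.RULE_FLATLINE
        else:  # rate spike: +25% step, then decay at ~8% per second
            factors = np.ones(n_blocks - a)
            decay = [1.25, 1.147, 1.053]
            for k, f in enumerate(decay):
                if k + 1 < len(factors):
                    factors[k + 1] = f
            # factors: block a stays 1.0, a+1 jumps to 1.25, then decays
            per_sample = np.repeat(factors, block)
            need = n - a * block
            if len(per_sample) < need:  # trailing samples past the block grid
                per_sample = np.concatenate(
                    (per_sample, np.full(need - len(per_sample), factors[-1])))
            x[a * block:] *= per_sample[:need]
            planted[a] = _eda.RULE_RATE
    rec = ChannelRecording(channel="EDA", start_time=gt.session_start, fs=fs, samples=x)
    return rec, planted


def simulate_acc(gt: NightGroundTruth, rng: np.random.Generator,
                 fs: float = 32.0, p_active_awake: float = 0.35,
                 arousals_per_night: float = 2.0) -> ChannelRecording:
    """3-axis accelerometer: movement bursts while awake, near rest asleep.

    Active seconds carry a band-limited oscillation on a random axis; sleep
    contains only sensor noise plus a few brief, low-amplitude arousals.
    Samples are quantized to the device's 1/64 g grid.
    """
    n = int(round((gt.session_end - gt.session_start) * fs))
    spb = int(round(fs))
    n_seconds = n // spb
    t_sec = gt.session_start + np.arange(n_seconds)
    asleep_sec = (t_sec >= gt.onset) & (t_sec < gt.wake)

    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0  # gravity
    acc += rng.normal(0.0, 0.002, size=(n, 3))

    active = (~asleep_sec) & (rng.random(n_seconds) < p_active_awake)
    # brief arousals inside the sleep period
    n_arousal = rng.poisson(arousals_per_night)
    sleep_idx = np.flatnonzero(asleep_sec)
    for _ in range(n_arousal):
        if len(sleep_idx) < 120:
            break
        s0 = int(rng.choice(sleep_idx[:-90]))
        dur = int(rng.integers(20, 90))
        pick = np.arange(s0, min(s0 + dur, n_seconds))
        active[pick] = rng.random(len(pick)) < 0.4
    amp = rng.uniform(0.05, 0.5, size=n_seconds)
    amp[asleep_sec] = np.minimum(amp[asleep_sec], 0.15)
    phase = rng.uniform(0, 2 * np.pi, size=n_seconds)
    axis = rng.integers(0, 3, size=n_seconds)
    tt = np.arange(spb) / fs
    for s in np.flatnonzero(active):
        burst = amp[s] * np.sin(2 * np.pi * 3.0 * tt + phase[s])
        acc[s * spb:(s + 1) * spb, axis[s]] += burst
    acc = np.rint(acc * 64.0) / 64.0  # device quantization
    return ChannelRecording(channel="ACC", start_time=gt.session_start, fs=fs,
                            samples=acc)


def simulate_temp(gt: NightGroundTruth, rng: np.random.Generator,
                  fs: float = 4.0, base_c: Optional[float] = None) -> ChannelRecording:
    """Skin temperature: rises after sleep onset, falls after waking."""
    n = int(round((gt.session_end - gt.session_start) * fs))
    t = gt.session_start + np.arange(n) / fs
    if base_c is None:
        base_c = float(rng.uniform(32.0, 33.5))
    tau = 900.0  # 15-minute transition
    rise = 1.0 / (1.0 + np.exp(-(t - gt.onset) / tau))
    fall = 1.0 / (1.0 + np.exp(-(t - gt.wake) / tau))
    x = base_c + 1.6 * (rise - fall)
    x += 0.2 * np.sin(2 * np.pi * (t - t[0]) / 7200.0 + rng.uniform(0, 2 * np.pi))
    x += rng.normal(0.0, 0.03, size=n)
    return ChannelRecording(channel="TEMP", start_time=gt.session_start, fs=fs,
                            samples=x)


# ---------------------------------------------------------------------------
# Night construction
# ---------------------------------------------------------------------------

def _planted_ibis(gt_start: float, gt_end: float, onset: float, wake: float,
                  hr_awake: float, hr_asleep: float, sd_awake: float,
                  sd_asleep: float, rng: np.random.Generator):
    """Beat times across the session with phase-dependent mean and SD."""
    times: List[np.ndarray] = []
    ibis: List[np.ndarray] = []
    t = gt_start
    for a, b, hr, sd in ((gt_start, onset, hr_awake, sd_awake),
                         (onset, wake, hr_asleep, sd_asleep),
                         (wake, gt_end, hr_awake, sd_awake)):
        mean_ms = 60000.0 / hr
        n_est = int(np.ceil((b - a) * 1000.0 / mean_ms * 1.2)) + 10
        seg = rng.normal(mean_ms, sd, size=n_est).clip(400.0, 1600.0)
        bt = a + np.cumsum(seg) / 1000.0
        keep = bt < b
        times.append(bt[keep])
        ibis.append(seg[keep])
    beat_times = np.concatenate(times)
    # re-derive IBIs from the concatenated beat stream so that every stated
    # IBI matches its beat-time gap exactly, including at phase boundaries
    out_ibis = np.empty_like(beat_times)
    out_ibis[0] = np.concatenate(ibis)[0]
    out_ibis[1:] = np.diff(beat_times) * 1000.0
    return beat_times, out_ibis


def _device_dropout_mask(beat_times: np.ndarray, gt, spec: CohortSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """True where the device would discard beats (motion-artifact segments)."""
    dropped = np.zeros(len(beat_times), dtype=bool)
    for (a, b, rate) in ((gt.session_start, gt.onset, spec.device_artifact_per_h_awake),
                         (gt.onset, gt.wake, spec.device_artifact_per_h_asleep),
                         (gt.wake, gt.session_end, spec.device_artifact_per_h_awake)):
        hours = (b - a) / 3600.0
        n_events = rng.poisson(rate * hours) if rate > 0 else 0
        for _ in range(n_events):
            start = rng.uniform(a, b)
            dur = rng.uniform(*spec.device_artifact_dur_s)
            dropped |= (beat_times >= start) & (beat_times < start + dur)
    return dropped


def _planted_feature_values(gt: NightGroundTruth) -> Dict[str, float]:
    """Ground-truth values of the features the label model may reference."""
    awake = (gt.beat_times < gt.onset) | (gt.beat_times >= gt.wake)
    feats = {
        "sleep_duration_min": gt.duration_min,
        "sleep_onset_latency_min": gt.latency_min,
    }
    for phase, mask in (("awake", awake), ("asleep", ~awake)):
        if mask.any():
            feats[f"hr_mean_{phase}"] = 60000.0 / float(np.mean(gt.ibis_ms[mask]))
            diffs = np.diff(gt.ibis_ms[mask])
            feats[f"rmssd_mean_{phase}"] = float(np.sqrt(np.mean(diffs ** 2))) if len(diffs) else 0.0
    return feats


def _build_night(spec: CohortSpec, pid: str, night_idx: int,
                 person: Dict[str, float]) -> NightGroundTruth:
    rng = participant_rng(spec.seed, pid, night_idx)
    day = _EPOCH_ANCHOR + night_idx * 86400.0
    bedtime = day + 23 * 3600.0 + person["bed_offset"] + rng.normal(0.0, 1200.0)
    latency = (2.0 + rng.exponential(spec.mean_latency_min - 2.0)) * 60.0
    onset = bedtime + latency
    duration = (person["sleep_h"] + rng.normal(0.0, spec.within_sleep_sd_h)) * 3600.0
    duration = max(duration, 3.0 * 3600.0)
    wake = onset + duration
    reported_wake = wake + float(np.clip(rng.normal(0.0, 300.0), -720.0, 720.0))
    session_start = bedtime - spec.wear_margin_h * 3600.0
    session_end = reported_wake + spec.wear_margin_h * 3600.0
    hr_asleep = person["hr_rest"] + rng.normal(0.0, 2.0)
    hr_awake = hr_asleep + 12.0 + rng.normal(0.0, 3.0)
    beat_times, ibis = _planted_ibis(session_start, session_end, onset, wake,
                                     hr_awake, hr_asleep,
                                     sd_awake=35.0, sd_asleep=55.0, rng=rng)
    gt = NightGroundTruth(
        participant_id=pid,
        night_date=_BASE_DATE + _dt.timedelta(days=night_idx + 1),
        session_start=session_start,
        session_end=session_end,
        bedtime=bedtime,
        onset=onset,
        wake=wake,
        reported_waketime=reported_wake,
        beat_times=beat_times,
        ibis_ms=ibis,
        device_dropped=np.zeros(len(ibis), dtype=bool),
        eda_block_rule=None,
        planted_features={},
    )
    gt.device_dropped = _device_dropout_mask(beat_times, gt, spec, rng)
    gt.planted_features = _planted_feature_values(gt)
    return gt


def _session_from_gt(spec: CohortSpec, gt: NightGroundTruth) -> RecordingSession:
    from .cardiac import IBISeries  # local import to avoid a cycle at import time

    rng = participant_rng(spec.seed, gt.participant_id, 1000000 + hash_night(gt))
    channels: Dict[str, ChannelRecording] = {}
    if "BVP" in spec.channels:
        # express beats as IBIs from the session start so cumulative sums in
        # the renderer reproduce the absolute planted beat times
        offsets = gt.beat_times - gt.session_start
        ibis_from_start = np.diff(np.concatenate(([0.0], offsets))) * 1000.0
        channels["BVP"] = simulate_bvp(ibis_from_start, fs=64.0,
                                       snr_db=spec.bvp_snr_db, rng=rng,
                                       start_time=gt.session_start)
    if "EDA" in spec.channels:
        rec, planted = simulate_eda(gt, rng, artifacts_per_night=spec.eda_artifacts_per_night)
        channels["EDA"] = rec
        gt.eda_block_rule = planted
    if "ACC" in spec.channels:
        channels["ACC"] = simulate_acc(gt, rng)
    if "TEMP" in spec.channels:
        channels["TEMP"] = simulate_temp(gt, rng)

    keep = ~gt.device_dropped
    bt = gt.beat_times[keep]
    ib = gt.ibis_ms[keep]
    contiguous = np.zeros(len(bt), dtype=bool)
    if len(bt) > 1:
        gaps_ms = np.diff(bt) * 1000.0
        contiguous[1:] = np.abs(gaps_ms - ib[1:]) <= 10.0
    device = IBISeries(beat_times=bt, ibis=ib, valid=np.ones(len(bt), bool),
                       contiguous=contiguous, source="device")
    diary = DiaryEntry(
        participant_id=gt.participant_id,
        night_date=gt.night_date,
        reported_bedtime=gt.bedtime,
        reported_waketime=gt.reported_waketime,
        sleep_quality=gt.response if gt.response else 3,
    )
    return RecordingSession(participant_id=gt.participant_id,
                            night_date=gt.night_date, channels=channels,
                            device_ibis=device, diary=diary)


def hash_night(gt: NightGroundTruth) -> int:
    return (gt.night_date - _BASE_DATE).days


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def generate_labels(features: pd.DataFrame, participant_ids: Sequence[str],
                    spec: CohortSpec, rng: np.random.Generator):
    """Draw 1-5 Likert responses from the planted latent model.

    ``latent = sum_f coeff_f * z_f + intercept_p + noise`` where ``z_f`` is
    the within-participant z-score (population SD) of feature ``f``; the
    latent is mapped to 1..5 through fixed quantile cuts, mimicking the
    skew toward "normal"/"good" responses typical of sleep diaries.
    """
    pids = pd.Series(list(participant_ids))
    missing = [f for f in spec.label_coeffs if f not in features.columns]
    if missing:
        raise ValidationError(f"label coefficients reference unknown features {missing}")
    latent = np.zeros(len(features))
    for f, coeff in spec.label_coeffs.items():
        v = features[f].to_numpy(dtype=float)
        z = np.zeros_like(v)
        for pid in pids.unique():
            m = (pids == pid).to_numpy()
            sd = np.std(v[m])
            if sd > 0:
                z[m] = (v[m] - np.mean(v[m])) / sd
        latent += coeff * z
    unique_pids = pids.unique()
    intercepts = dict(zip(unique_pids,
                          rng.normal(0.0, spec.intercept_sd, size=len(unique_pids))))
    latent += pids.map(intercepts).to_numpy()
    latent += rng.normal(0.0, spec.label_noise_sd, size=len(latent))
    cuts = np.quantile(latent, spec.likert_cuts) if len(latent) > 4 else np.array([-1.5, -0.5, 0.5, 1.5])
    responses = np.digitize(latent, cuts) + 1
    return responses.astype(int), latent


# ---------------------------------------------------------------------------
# Cohort drivers
# ---------------------------------------------------------------------------

def _person_effects(spec: CohortSpec, pid: str) -> Dict[str, float]:
    rng = participant_rng(spec.seed, pid, 999)
    return {
        "sleep_h": spec.mean_sleep_h + rng.normal(0.0, spec.between_sleep_sd_h),
        "bed_offset": rng.normal(0.0, 2700.0),
        "hr_rest": rng.normal(62.0, 5.0),
        "age": int(rng.integers(19, 36)),
        "gender": "F" if rng.random() < 5 / 16 else "M",
    }


def cohort_ground_truth(spec: CohortSpec) -> List[NightGroundTruth]:
    """Plant all nights (no signal rendering) and draw the responses."""
    gts: List[NightGroundTruth] = []
    for pid in spec.participant_ids():
        person = _person_effects(spec, pid)
        for k in range(spec.n_nights):
            gts.append(_build_night(spec, pid, k, person))
    feat_names = sorted({f for gt in gts for f in gt.planted_features})
    table = pd.DataFrame([{f: gt.planted_features.get(f, np.nan) for f in feat_names}
                          for gt in gts])
    label_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 424242])
    responses, latent = generate_labels(table, [gt.participant_id for gt in gts],
                                        spec, label_rng)
    for gt, r, l in zip(gts, responses, latent):
        gt.response = int(r)
        gt.latent = float(l)
    return gts


def iter_cohort(spec: CohortSpec) -> Iterator[Tuple[RecordingSession, DiaryEntry, NightGroundTruth]]:
    """Yield sessions one night at a time (memory-friendly for big cohorts)."""
    for gt in cohort_ground_truth(spec):
        session = _session_from_gt(spec, gt)
        yield session, session.diary, gt


def simulate_cohort(spec: CohortSpec):
    """Materialize a full cohort: (sessions, diaries, ground truths)."""
    sessions, diaries, gts = [], [], []
    for session, diary, gt in iter_cohort(spec):
        sessions.append(session)
        diaries.append(diary)
        gts.append(gt)
    return sessions, diaries, gts


def demographics(spec: CohortSpec) -> pd.DataFrame:
    """Planted per-participant age and gender."""
    rows = []
    for pid in spec.participant_ids():
        person = _person_effects(spec, pid)
        rows.append({"participant_id": pid, "age": person["age"],
                     "gender": person["gender"]})
    return pd.DataFrame(rows)


def simulate_observations(spec: CohortSpec):
    """Feature-level cohort: per-night 52-feature vectors plus responses.

    Features follow a participant-random-effects model (between-participant
    SD 1, within-participant SD 1 on an arbitrary scale); responses come
    from :func:`generate_labels` with the spec's planted coefficients.
    Returns ``(observations, truth)`` where observations is a feature-table
    DataFrame and truth holds the planted coefficients and latents.
    """
    from .dataset import FEATURE_NAMES

    pids = spec.participant_ids()
    rows = []
    identities = []
    for pid in pids:
        rng = participant_rng(spec.seed, pid, 777)
        means = rng.normal(0.0, 1.0, size=len(FEATURE_NAMES))
        nights = means + rng.normal(0.0, 1.0, size=(spec.n_nights, len(FEATURE_NAMES)))
        rows.append(nights)
        identities += [(pid, _BASE_DATE + _dt.timedelta(days=k + 1))
                       for k in range(spec.n_nights)]
    feats = pd.DataFrame(np.vstack(rows), columns=FEATURE_NAMES)
    label_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 424242])
    responses, latent = generate_labels(feats, [pid for pid, _ in identities],
                                        spec, label_rng)
    obs = feats.copy()
    obs.insert(0, "participant_id", [pid for pid, _ in identities])
    obs.insert(1, "night_date", [d for _, d in identities])
    obs["response"] = responses
    truth = {"coeffs": dict(spec.label_coeffs), "latent": latent,
             "noise_sd": spec.label_noise_sd}
    return obs, truth
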