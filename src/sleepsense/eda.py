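"""Electrodermal-activity validation rules and the 12 EDA features.

Skin conductance recorded at the wrist is only meaningful while the
electrodes make proper contact and the sensor is actually measuring.  Three
per-second validity rules are applied, in order, to 1-second blocks aligned
to the recording start:

1. *low amplitude* — samples below 0.05 microsiemens imply lost skin contact;
2. *flatline* — a second in which the signal changes by no more than
   0.01 microsiemens implies the sensor did not measure;
3. *rate violation* — skin conductance can physiologically change by at most
   +20% / -10% per second, so a 1-second step outside ``[0.9x, 1.2x]`` of the
   starting amplitude ``x`` is an artifact.

Features are level statistics (mean/max/min, microsiemens) over valid samples
and least-squares slopes (microsiemens/min) over 5-minute windows with
2.5-minute overlap, each split by awake/asleep phase.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional

import numpy as np

from .signal_io import ChannelRecording, ValidationError

__all__ = ["EDAValidityMask", "validate_eda", "eda_features", "rule_hit_table",
           "LOW_AMPLITUDE_US", "FLATLINE_DELTA_US", "MAX_RISE", "MAX_FALL"]

LOW_AMPLITUDE_US = 0.05
FLATLINE_DELTA_US = 0.01
MAX_RISE = 0.20   # +20% per second
MAX_FALL = 0.10   # -10% per second

RULE_NONE = 0
RULE_LOW_AMPLITUDE = 1
RULE_FLATLINE = 2
RULE_RATE = 3

RULE_NAMES = {RULE_NONE: "none", RULE_LOW_AMPLITUDE: "low_amplitude",
              RULE_FLATLINE: "flatline", RULE_RATE: "rate_violation"}


@dataclasses.dataclass
class EDAValidityMask:
    """Per-sample validity with the rule that invalidated each sample."""

    valid: np.ndarray      # bool per sample
    rule_hit: np.ndarray   # int per sample (RULE_* codes)

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        self.rule_hit = np.asarray(self.rule_hit, dtype=int)
        if len(self.valid) != len(self.rule_hit):
            raise ValidationError("mask arrays must have equal length")
        if np.any(self.valid != (self.rule_hit == RULE_NONE)):
            raise ValidationError("valid must hold exactly where no rule hit")

    def __len__(self) -> int:
        return len(self.valid)

    def block_invalid(self, block_samples: int = 4) -> np.ndarray:
        """Per-1-second-block invalidity (any sample in the block invalid)."""
        n_blocks = len(self.valid) // block_samples
        trimmed = ~self.valid[: n_blocks * block_samples]
        return trimmed.reshape(n_blocks, block_samples).any(axis=1)


def validate_eda(recording: ChannelRecording) -> EDAValidityMask:
    """Apply the three validity rules on 1-second blocks.

    Rules are evaluated in order 1 -> 2 -> 3 and their union is removed; the
    recorded ``rule_hit`` is the first rule that fired for a sample.  Rule 3
    compares the amplitude at the start of each block with the amplitude one
    second later (the start of the next block); the final block, having no
    successor, is only subject to rules 1 and 2.
    """
    if recording.channel != "EDA":
        raise ValidationError(f"validate_eda expects an EDA channel, got {recording.channel}")
    x = recording.samples
    n = len(x)
    block = int(round(recording.fs))  # samples per 1-second block
    rule_hit = np.zeros(n, dtype=int)

    # rule 1: per-sample low amplitude
    low = x < LOW_AMPLITUDE_US
    rule_hit[low] = RULE_LOW_AMPLITUDE

    n_blocks = n // block
    if n_blocks:
        xb = x[: n_blocks * block].reshape(n_blocks, block)
        # rule 2: flatline second (max - min <= 0.01 uS)
        flat = (xb.max(axis=1) - xb.min(axis=1)) <= FLATLINE_DELTA_US
        # rule 3: amplitude one second after the block start outside the
        # physiological band [0.9x, 1.2x]
        starts = xb[:, 0]
        nxt = np.empty(n_blocks)
        nxt[:-1] = starts[1:]
        rate = np.zeros(n_blocks, dtype=bool)
        if n_blocks > 1:
            s = starts[:-1]
            e = nxt[:-1]
            rate[:-1] = (e > (1.0 + MAX_RISE) * s) | (e < (1.0 - MAX_FALL) * s)
        for code, hits in ((RULE_FLATLINE, flat), (RULE_RATE, rate)):
            for b in np.flatnonzero(hits):
                seg = rule_hit[b * block:(b + 1) * block]
                seg[seg == RULE_NONE] = code
    valid = rule_hit == RULE_NONE
    return EDAValidityMask(valid=valid, rule_hit=rule_hit)


def rule_hit_table(recording: ChannelRecording, mask: EDAValidityMask):
    """Per-second audit table: which rule (if any) fired in each block."""
    import pandas as pd

    block = int(round(recording.fs))
    n_blocks = len(mask) // block
    codes = mask.rule_hit[: n_blocks * block].reshape(n_blocks, block)
    first = np.zeros(n_blocks, dtype=int)
    hit_any = (codes > 0).any(axis=1)
    for b in np.flatnonzero(hit_any):
        nz = codes[b][codes[b] > 0]
        first[b] = nz[0]
    return pd.DataFrame({
        "second_start": recording.start_time + np.arange(n_blocks, dtype=float),
        "valid": ~hit_any,
        "rule_hit": [RULE_NAMES[c] for c in first],
    })


def _window_slopes(times: np.ndarray, values: np.ndarray, valid: np.ndarray,
                   t0: float, t_end: float, window_s: float, step_s: float,
                   min_valid_frac: float, fs: float):
    """Least-squares slope per window (units per minute) and window midpoints."""
    slopes, mids = [], []
    start = t0
    expected = window_s * fs
    while start + window_s <= t_end + 1e-9:
        sel = (times >= start) & (times < start + window_s) & valid
        n = int(sel.sum())
        if n >= 2 and n >= min_valid_frac * expected:
            t = times[sel] - start
            v = values[sel]
            slope_per_s = np.polyfit(t, v, 1)[0]
            slopes.append(slope_per_s * 60.0)
            mids.append(start + window_s / 2.0)
        start += step_s
    return np.asarray(slopes), np.asarray(mids)


def eda_features(recording: ChannelRecording, mask: EDAValidityMask,
                 sleep_period, window_s: float = 300.0, step_s: float = 150.0,
                 min_valid_frac: float = 0.5, awake_window=None) -> Dict[str, float]:
    """The 12 EDA features: level and slope statistics per phase.

    Level statistics use valid samples only.  Slopes are ordinary
    least-squares fits per 5-minute window (2.5-minute overlap) computed on
    valid samples; windows with under 50% valid samples are skipped.  Windows
    are assigned awake/asleep by midpoint.  A phase with no valid data yields
    NaN for its slots.
    """
    if recording.channel != "EDA":
        raise ValidationError(f"eda_features expects an EDA channel, got {recording.channel}")
    if len(mask) != recording.n_samples:
        raise ValidationError("mask length must equal the sample count")
    from .signal_io import phase_masks

    times = recording.times()
    x = recording.samples
    awake, asleep = phase_masks(times, sleep_period.onset, sleep_period.wake,
                                awake_window)
    slopes, mids = _window_slopes(times, x, mask.valid, recording.start_time,
                                  recording.end_time, window_s, step_s,
                                  min_valid_frac, recording.fs)
    slope_awake, slope_asleep = phase_masks(mids, sleep_period.onset,
                                            sleep_period.wake, awake_window)

    features: Dict[str, float] = {}
    for phase, p_mask, s_mask in (("awake", awake, slope_awake),
                                  ("asleep", asleep, slope_asleep)):
        lv = x[p_mask & mask.valid]
        for stat, fn in (("mean", np.mean), ("max", np.max), ("min", np.min)):
            features[f"eda_level_{stat}_{phase}"] = float(fn(lv)) if len(lv) else float("nan")
        sv = slopes[s_mask] if len(slopes) else np.empty(0)
        for stat, fn in (("mean", np.mean), ("max", np.max), ("min", np.min)):
            features[f"eda_slope_{stat}_{phase}"] = float(fn(sv)) if len(sv) else float("nan")
    return features
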