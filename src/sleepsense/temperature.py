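"""The 12 skin-temperature features.

Skin temperature tracks the circadian rhythm: distal skin warms after sleep
onset while the core cools.  Level statistics (mean/max/min, deg C) are
computed on the raw 4 Hz signal per phase; slopes (deg C/min) are ordinary
least-squares fits over 5-minute windows with 2.5-minute overlap, assigned to
awake/asleep by window midpoint.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .eda import _window_slopes
from .signal_io import ChannelRecording, ValidationError

__all__ = ["temp_features"]


def temp_features(recording: ChannelRecording, sleep_period,
                  window_s: float = 300.0, step_s: float = 150.0,
                  awake_window=None) -> Dict[str, float]:
    """Level and slope statistics of skin temperature per phase."""
    from .signal_io import phase_masks

    if recording.channel != "TEMP":
        raise ValidationError(f"temp_features expects a TEMP channel, got {recording.channel}")
    times = recording.times()
    x = recording.samples
    awake, asleep = phase_masks(times, sleep_period.onset, sleep_period.wake,
                                awake_window)
    all_valid = np.ones(len(x), dtype=bool)
    slopes, mids = _window_slopes(times, x, all_valid, recording.start_time,
                                  recording.end_time, window_s, step_s,
                                  min_valid_frac=0.5, fs=recording.fs)
    slope_awake, slope_asleep = phase_masks(mids, sleep_period.onset,
                                            sleep_period.wake, awake_window)

    features: Dict[str, float] = {}
    for phase, p_mask, s_mask in (("awake", awake, slope_awake),
                                  ("asleep", asleep, slope_asleep)):
        lv = x[p_mask]
        for stat, fn in (("mean", np.mean), ("max", np.max), ("min", np.min)):
            features[f"temp_level_{stat}_{phase}"] = float(fn(lv)) if len(lv) else float("nan")
        sv = slopes[s_mask] if len(slopes) else np.empty(0)
        for stat, fn in (("mean", np.mean), ("max", np.max), ("min", np.min)):
            features[f"temp_slope_{stat}_{phase}"] = float(fn(sv)) if len(sv) else float("nan")
    return features
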