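"""Band-pass response, beat detection, HRV metrics and windowing."""

import numpy as np
import pytest

from sleepsense.cardiac import (AdjustmentReference, IBISeries, aggregate_cardiac,
                                bandpass_bvp, detect_beats, hrv_metrics,
                                window_ibis)
from sleepsense.actigraphy import SleepPeriod
from sleepsense.signal_io import ChannelRecording, ValidationError
from sleepsense.synthetic import simulate_bvp

FS = 64.0


def _sine(freq, seconds=60.0, fs=FS, amp=1.0, offset=0.0):
    t = np.arange(int(seconds * fs)) / fs
    return ChannelRecording("BVP", 0.0, fs, offset + amp * np.sin(2 * np.pi * freq * t))


def _steady_amplitude(rec, discard_s=5.0):
    x = rec.samples[int(discard_s * rec.fs):-int(discard_s * rec.fs)]
    return np.ptp(x) / 2.0


class TestBandpass:
    def test_dc_removed(self):
        rec = ChannelRecording("BVP", 0.0, FS, np.full(int(30 * FS), 100.0))
        out = bandpass_bvp(rec)
        assert np.max(np.abs(out.samples[int(5 * FS):-int(5 * FS)])) < 1e-6 * 100.0

    def test_pulse_band_passes(self):
        amp = _steady_amplitude(bandpass_bvp(_sine(1.2)))
        assert 0.9 <= amp <= 1.0

    def test_drift_attenuated_20db(self):
        amp = _steady_amplitude(bandpass_bvp(_sine(0.05, seconds=120.0)), discard_s=20.0)
        assert amp <= 0.1

    def test_high_frequency_attenuated_20db(self):
        amp = _steady_amplitude(bandpass_bvp(_sine(25.0)))
        assert amp <= 0.1

    def test_low_rate_infeasible(self):
        rec = ChannelRecording("BVP", 0.0, 16.0, np.zeros(100))
        with pytest.raises(ValidationError):
            bandpass_bvp(rec)


class TestDetectBeats:
    def test_noiseless_constant_rhythm_within_one_sample(self):
        ibis = np.full(70, 800.0)
        rec = simulate_bvp(ibis, fs=FS, snr_db=80.0,
                           rng=np.random.default_rng(0))
        det = detect_beats(bandpass_bvp(rec))
        assert len(det) > 60
        core = det.ibis[2:-2]
        assert np.all(np.abs(core - 800.0) <= 1000.0 / FS + 1e-9)

    def test_constant_signal_yields_empty_series(self):
        rec = ChannelRecording("BVP", 0.0, FS, np.zeros(int(60 * FS)))
        det = detect_beats(rec)
        assert len(det) == 0

    def test_pure_noise_fails_quality_gate(self, rng):
        rec = ChannelRecording("BVP", 0.0, FS, rng.normal(size=int(600 * FS)))
        det = detect_beats(bandpass_bvp(rec))
        windows = window_ibis(det, t0=0.0, t_end=600.0)
        assert all(not w.quality_ok for w in windows)


class TestHRVMetrics:
    def test_constant_rhythm_no_variability(self):
        m = hrv_metrics([800.0] * 10)
        assert m["hr"] == pytest.approx(75.0)
        assert m["rmssd"] == m["sdnn"] == m["sd2"] == 0.0

    def test_rmssd_direct_formula(self):
        m = hrv_metrics([800.0, 810.0, 790.0, 805.0])
        assert m["rmssd"] == pytest.approx(np.sqrt((10**2 + 20**2 + 15**2) / 3),
                                           rel=1e-9)

    def test_too_few_ibis(self):
        with pytest.raises(ValidationError):
            hrv_metrics([800.0, 810.0])

    def test_sd2_matches_rotated_poincare_oracle(self, rng):
        # SD2 is the population SD of (x_i + x_{i+1})/sqrt(2), i.e. the
        # dispersion along the identity line of the Poincare plot
        for _ in range(200):
            ibis = rng.uniform(500, 1200, size=rng.integers(3, 60))
            m = hrv_metrics(ibis)
            rotated = (ibis[:-1] + ibis[1:]) / np.sqrt(2)
            # oracle via the identity 2*SDNN^2 = SD1^2 + SD2^2 with
            # SD1 = SDSD/sqrt(2), computed from scratch:
            sd1 = np.std(np.diff(ibis)) / np.sqrt(2)
            oracle = np.sqrt(max(0.0, 2 * np.std(ibis) ** 2 - sd1 ** 2))
            assert m["sd2"] == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_brute_force_equivalence_many_windows(self, rng):
        for _ in range(1000):
            ibis = rng.uniform(400, 1500, size=rng.integers(3, 40))
            m = hrv_metrics(ibis)
            n = len(ibis)
            mean = sum(ibis) / n
            assert m["hr"] == pytest.approx(60000.0 / mean, rel=1e-9)
            d = [ibis[i + 1] - ibis[i] for i in range(n - 1)]
            assert m["rmssd"] == pytest.approx(
                (sum(x * x for x in d) / len(d)) ** 0.5, rel=1e-9)
            sdnn = (sum((x - mean) ** 2 for x in ibis) / n) ** 0.5
            assert m["sdnn"] == pytest.approx(sdnn, rel=1e-9)


class TestWindowing:
    def _series(self, ibis_ms, start=0.0, contiguous=True):
        times = start + np.cumsum(ibis_ms) / 1000.0
        c = np.ones(len(ibis_ms), dtype=bool)
        c[0] = False
        if not contiguous:
            c[len(c) // 2] = False
        return IBISeries(times, np.asarray(ibis_ms), np.ones(len(ibis_ms), bool),
                         c, source="device")

    def test_ten_minutes_three_windows(self):
        s = self._series([800.0] * 750)  # 600 s of beats
        windows = window_ibis(s, t0=0.0, t_end=600.0)
        assert [w.start for w in windows] == [0.0, 150.0, 300.0]
        assert all(w.quality_ok for w in windows)

    def test_missing_beat_drops_window(self):
        ibis = [800.0] * 800  # 640 s of beats
        times = np.cumsum(ibis) / 1000.0
        # remove one beat mid-stream: gap of 1600 ms vs stated 800 ms
        keep = np.ones(800, bool)
        keep[200] = False
        times = times[keep]
        ibis = np.asarray(ibis)[keep]
        contiguous = np.ones(len(times), bool)
        contiguous[0] = False
        gaps = np.diff(times) * 1000.0
        contiguous[1:] = np.abs(gaps - ibis[1:]) <= 10.0
        s = IBISeries(times, ibis, np.ones(len(times), bool), contiguous)
        windows = window_ibis(s, t0=0.0, t_end=float(times[-1]))
        bad = [w for w in windows if w.start <= 160.0 < w.start + 300.0]
        assert bad and all(not w.quality_ok for w in bad)
        assert any(w.quality_ok for w in windows)

    def test_empty_series(self):
        s = IBISeries(np.empty(0), np.empty(0), np.empty(0, bool),
                      np.empty(0, bool))
        assert window_ibis(s) == []


class TestAdjustment:
    def _table(self, rng, n=200):
        import pandas as pd
        return pd.DataFrame({
            "gender": rng.choice(["F", "M"], size=n),
            "age": rng.integers(19, 36, size=n),
            "start": rng.uniform(0, 86400, size=n),
            "rmssd": rng.normal(40, 12, size=n),
            "sdnn": rng.normal(55, 15, size=n),
            "sd2": rng.normal(70, 18, size=n),
        })

    def test_value_at_stratum_mean_maps_to_zero(self, rng):
        tab = self._table(rng)
        ref = AdjustmentReference().fit(tab)
        # an unseen stratum falls back to the pooled statistics
        pooled_mean = tab["rmssd"].mean()
        z = ref.adjust(pooled_mean, "rmssd", "X", 99, 0.0)  # unseen stratum
        assert z == pytest.approx(0.0, abs=1e-9)

    def test_single_stratum_zscore(self):
        import pandas as pd
        tab = pd.DataFrame({
            "gender": ["M"] * 20, "age": [25] * 20, "start": [3600.0] * 20,
            "rmssd": np.concatenate((np.full(10, 40.0), np.full(10, 60.0))),
            "sdnn": np.full(20, 55.0), "sd2": np.full(20, 70.0),
        })
        ref = AdjustmentReference().fit(tab)
        assert ref.adjust(60.0, "rmssd", "M", 25, 3600.0) == pytest.approx(1.0)

    def test_adjusted_strata_are_standardized(self, rng):
        tab = self._table(rng, n=2000)
        ref = AdjustmentReference().fit(tab)
        keys = [AdjustmentReference.stratum_key(g, a, s)
                for g, a, s in zip(tab["gender"], tab["age"], tab["start"])]
        tab = tab.assign(key=keys)
        for key, grp in tab.groupby("key"):
            if len(grp) < ref.min_stratum:
                continue
            z = np.array([ref.adjust(v, "sdnn", g, a, s) for v, g, a, s in
                          zip(grp["sdnn"], grp["gender"], grp["age"], grp["start"])])
            assert np.mean(z) == pytest.approx(0.0, abs=1e-9)
            assert np.std(z) == pytest.approx(1.0, abs=1e-9)

    def test_empty_reference_raises(self):
        ref = AdjustmentReference()
        with pytest.raises(ValidationError):
            ref.adjust(1.0, "rmssd", "M", 25, 0.0)


class TestAggregate:
    def _window(self, start, hr=60.0, rmssd=30.0):
        from sleepsense.cardiac import CardiacWindow
        return CardiacWindow(start=start, duration=300.0, hr=hr, rmssd=rmssd,
                             sdnn=40.0, sd2=50.0, n_beats=300, quality_ok=True)

    def test_identical_windows_min_equals_max(self):
        sp = SleepPeriod(onset=1000.0, wake=20000.0, latency_min=5.0,
                         duration_min=316.0)
        feats = aggregate_cardiac([self._window(2000.0)] * 3, sp)
        assert feats["hr_min_asleep"] == feats["hr_mean_asleep"] == feats["hr_max_asleep"]

    def test_hand_built_aggregates(self):
        sp = SleepPeriod(onset=10000.0, wake=50000.0, latency_min=5.0,
                         duration_min=666.0)
        ws = [self._window(0.0, hr=70.0), self._window(12000.0, hr=55.0),
              self._window(14000.0, hr=65.0)]
        feats = aggregate_cardiac(ws, sp)
        assert feats["hr_mean_awake"] == pytest.approx(70.0)
        assert feats["hr_mean_asleep"] == pytest.approx(60.0)
        assert feats["hr_max_asleep"] == pytest.approx(65.0)
        assert feats["hr_min_asleep"] == pytest.approx(55.0)

    def test_no_asleep_windows_gives_missing(self):
        sp = SleepPeriod(onset=1e6, wake=2e6, latency_min=5.0, duration_min=100.0)
        feats = aggregate_cardiac([self._window(0.0)], sp)
        asleep = [k for k in feats if k.endswith("_asleep")]
        assert len(asleep) == 12
        assert all(np.isnan(feats[k]) for k in asleep)
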