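import numpy as np
import pytest

import betarebound as br
from betarebound.rebound_detection import BandPowerSeries

FS = 500.0


def _naive_scan(power, thr, schedule):
    """Independent oracle: loop over every (epoch, window) pair.

    An epoch (end-stamped) belongs to a window when its data interval
    [t - epoch_len, t] lies inside the window.
    """
    el = power.epoch_len
    detections, rest = [], []
    for (w0, w1) in br.active_windows(schedule):
        first = None
        for t, p in zip(power.times, power.power):
            if w0 - 1e-9 <= t - el and t <= w1 + 1e-9 and p > thr:
                first = t
                break
        detections.append(first)
    for i, (w0, w1) in enumerate(br.idle_windows(schedule)):
        for t, p in zip(power.times, power.power):
            if w0 - 1e-9 <= t - el and t <= w1 + 1e-9 and p > thr:
                rest.append(i)
                break
    return detections, rest


class TestEpochPower:
    def test_constant_input(self):
        p = br.epoch_power(np.full(int(10 * FS), 3.0), FS)
        assert np.allclose(p.power, 9.0)

    def test_sinusoid_mean_square(self):
        t = np.arange(int(10 * FS)) / FS
        p = br.epoch_power(np.sin(2 * np.pi * 20 * t), FS, epoch_len=1.0)
        assert np.allclose(p.power, 0.5, atol=1e-3)

    @pytest.mark.parametrize(
        "n_sec, epoch, stride, expected",
        [(300, 1.0, 0.1, 2991), (10, 1.0, 0.1, 91), (5, 1.0, 0.9, 5)],
    )
    def test_epoch_count_formula(self, n_sec, epoch, stride, expected):
        x = np.zeros(int(n_sec * FS))
        p = br.epoch_power(x, FS, epoch, stride)
        assert len(p) == expected
        # enumeration oracle over sample indices
        ne, ns = int(epoch * FS), int(stride * FS)
        count = len(range(0, len(x) - ne + 1, ns))
        assert len(p) == count

    def test_timestamps_are_epoch_ends_with_constant_stride(self):
        p = br.epoch_power(np.zeros(int(5 * FS)), FS)
        assert p.times[0] == pytest.approx(1.0)
        assert np.allclose(np.diff(p.times), 0.1)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            br.epoch_power(np.zeros(100), FS, epoch_len=1.0)


class TestCalibrate:
    def test_constant_power_gives_threshold_at_mean(self):
        p = br.epoch_power(np.full(int(5 * FS), 2.0), FS)
        th = br.calibrate(p)
        assert th.th == pytest.approx(4.0)
        assert th.sd == 0.0

    def test_hand_computed_example(self):
        p = BandPowerSeries(np.array([1.0, 1.1, 1.2]),
                            np.array([1.0, 2.0, 3.0]), 1.0, 0.1)
        th = br.calibrate(p, k=3)
        # mean 2, sample sd 1 -> Th = 5
        assert th.th == pytest.approx(5.0)

    def test_matches_independent_two_pass_computation(self):
        rng = np.random.default_rng(8)
        vals = rng.gamma(2.0, 3.0, size=10_000)
        p = BandPowerSeries(1.0 + 0.1 * np.arange(vals.size), vals, 1.0, 0.1)
        th = br.calibrate(p)
        mean = sum(vals) / vals.size
        var = sum((v - mean) ** 2 for v in vals) / (vals.size - 1)
        assert th.th == pytest.approx(mean + 3 * np.sqrt(var), rel=1e-12)

    def test_too_few_epochs_rejected(self):
        p = BandPowerSeries(np.array([1.0]), np.array([1.0]), 1.0, 0.1)
        with pytest.raises(ValueError, match="at least 2"):
            br.calibrate(p)


def _random_case(rng):
    wait = float(rng.choice([0, 10]))
    phase = float(rng.choice([5, 10]))
    total = wait + phase * rng.integers(2, 9)
    sched = br.build_schedule(
        "MIV", total, wait, phase, str(rng.choice(["ACTIVE", "IDLE"]))
    )
    n = int((total - 1.0) / 0.1) + 1
    power = BandPowerSeries(
        1.0 + 0.1 * np.arange(n), rng.lognormal(0.0, 1.0, size=n), 1.0, 0.1
    )
    thr = float(np.quantile(power.power, rng.uniform(0.5, 0.99)))
    return power, thr, sched


class TestDetect:
    def test_all_below_threshold(self, default_schedule):
        n = int(299.0 / 0.1) + 1
        power = BandPowerSeries(1.0 + 0.1 * np.arange(n), np.ones(n), 1.0, 0.1)
        res = br.detect(power, 5.0, default_schedule)
        assert res.n_detected == 0
        assert res.rest_crossing_windows == ()

    def test_single_crossing_latency(self, default_schedule):
        n = int(299.0 / 0.1) + 1
        times = 1.0 + 0.1 * np.arange(n)
        vals = np.ones(n)
        vals[np.argmin(np.abs(times - 32.0))] = 10.0  # 2 s into first window
        power = BandPowerSeries(times, vals, 1.0, 0.1)
        res = br.detect(power, 5.0, default_schedule)
        assert res.windows[0].detected
        assert res.windows[0].latency_ms == pytest.approx(2000.0)
        assert res.n_detected == 1

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            power, thr, sched = _random_case(rng)
            res = br.detect(power, thr, sched)
            naive_det, naive_rest = _naive_scan(power, thr, sched)
            got = [w.first_crossing_time if w.detected else None
                   for w in res.windows]
            assert got == pytest.approx(naive_det)
            assert list(res.rest_crossing_windows) == naive_rest

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(5)
        power, thr, sched = _random_case(rng)
        lo = br.detect(power, thr, sched)
        hi = br.detect(power, thr * 2, sched)
        assert hi.n_detected <= lo.n_detected
        assert len(hi.rest_crossing_windows) <= len(lo.rest_crossing_windows)
        # every window detected at the high threshold is detected at the low
        for wl, wh in zip(lo.windows, hi.windows):
            assert wl.detected or not wh.detected

    def test_schedule_beyond_series_rejected(self, default_schedule):
        power = BandPowerSeries(
            1.0 + 0.1 * np.arange(100), np.ones(100), 1.0, 0.1
        )
        with pytest.raises(ValueError, match="ends at"):
            br.detect(power, 1.0, default_schedule)


class TestFalseAlarmControl:
    def test_exceedance_fraction_decreases_with_k(self, calibration_schedule):
        # stationary calibration noise: higher k -> rarer crossings
        rates = {k: [] for k in (1, 2, 3, 4)}
        for seed in range(10):
            rec, _ = br.generate_session(
                calibration_schedule, br.SynthesisParams(seed=300 + seed)
            )
            filt = br.bandpass(br.laplacian(rec), rec.fs, br.beta_spec())
            power = br.epoch_power(filt, rec.fs)
            for k in rates:
                th = br.calibrate(power, k=k)
                rates[k].append(np.mean(power.power > th.th))
        means = [np.mean(rates[k]) for k in (1, 2, 3, 4)]
        assert means == sorted(means, reverse=True)
        assert all(m1 > m2 for m1, m2 in zip(means, means[1:]))
        assert means[2] < 0.05  # k=3 exceedance is small
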