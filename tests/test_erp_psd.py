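import numpy as np
import pytest

import betarebound as br
from betarebound.erp_psd import band_mean, compute_erp, welch

FS = 500.0


@pytest.fixture(scope="module")
def stationary_session():
    sched = br.preset_schedule("no_wait")
    params = br.SynthesisParams(seed=31, erd_gain=1.0, ers_gain=1.0)
    rec, _ = br.generate_session(sched, params)
    return rec, sched


@pytest.fixture(scope="module")
def rebound_session():
    # fixed 1.5 s rebound latency in every window so the burst interval is
    # the same across segments
    sched = br.preset_schedule("default")
    params = br.SynthesisParams(seed=32, ers_latency_dist=(1.5, 0.0),
                                spurious_rate=0.0)
    rec, gt = br.generate_session(sched, params)
    return rec, sched, gt


class TestComputeERP:
    def test_baseline_identity_is_pointwise(self, rebound_session):
        rec, sched, _ = rebound_session
        erp = compute_erp(rec, sched)["Cz"]
        assert np.allclose(
            erp.corrected_power, erp.p_t - erp.p_baseline, atol=0.0
        )

    def test_stationary_session_has_near_zero_erp(self, stationary_session):
        # active-vs-baseline power differences are statistically
        # indistinguishable from zero when no ERD/ERS is injected
        from scipy import stats

        rec, sched = stationary_session
        erp = compute_erp(rec, sched)["Cz"]
        diffs = erp.segment_means - erp.segment_baselines
        assert stats.ttest_1samp(diffs, 0.0).pvalue > 0.01

    def test_rebound_shows_positive_excursion_at_burst(self, rebound_session):
        rec, sched, gt = rebound_session
        erp = compute_erp(rec, sched)["Cz"]
        burst = (erp.times >= 1.5) & (erp.times < 2.5)
        late = (erp.times >= 4.0) & (erp.times < 9.0)
        assert erp.corrected_power[burst].mean() > 0
        assert (
            erp.corrected_power[burst].mean()
            > 5 * abs(erp.corrected_power[late].mean())
        )

    def test_power_is_quadratic_in_amplitude(self, rebound_session):
        rec, sched, _ = rebound_session
        doubled = br.EEGRecording(
            rec.samples * 2.0, rec.fs, rec.channel_labels
        )
        e1 = compute_erp(rec, sched)["C1"]
        e2 = compute_erp(doubled, sched)["C1"]
        assert np.allclose(e2.corrected_power, 4.0 * e1.corrected_power,
                           rtol=1e-9)

    def test_window_without_baseline_is_skipped_with_warning(self):
        # active-first with no wait: the first window has no preceding rest
        sched = br.build_schedule("MIV", 60, 0, 10, "ACTIVE")
        rec, _ = br.generate_session(sched, br.SynthesisParams(seed=33))
        with pytest.warns(UserWarning, match="skipped"):
            erp = compute_erp(rec, sched)["Cz"]
        assert erp.n_segments == len(br.active_windows(sched)) - 1


class TestWelch:
    def test_parseval_on_white_noise(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(int(60 * FS))
        est = welch(x, FS)
        integral = np.trapezoid(est.density_linear, est.freqs)
        assert integral == pytest.approx(np.var(x), rel=0.05)

    def test_sinusoid_peak_location(self):
        t = np.arange(int(10 * FS)) / FS
        est = welch(np.sin(2 * np.pi * 20 * t), FS)
        peak = est.freqs[np.argmax(est.density_linear)]
        assert abs(peak - 20.0) <= 2.0  # 0.5 s window -> 2 Hz resolution

    def test_zero_signal_is_identically_zero(self):
        est = welch(np.zeros(int(5 * FS)), FS)
        assert np.all(est.density_linear == 0.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch(np.zeros(100), FS)

    def test_overlap_averaging_reduces_variance(self):
        # Welch (many averaged segments) vs the single periodogram,
        # variance across 30 seeded white-noise draws per frequency bin
        n = int(4 * FS)
        welch_vals, perio_vals = [], []
        for seed in range(30):
            x = np.random.default_rng(100 + seed).standard_normal(n)
            est = welch(x, FS)
            sel = (est.freqs >= 8) & (est.freqs <= 30)
            welch_vals.append(est.density_linear[sel].mean())
            from scipy.signal import periodogram

            f, p = periodogram(x, fs=FS)
            perio_vals.append(p[(f >= 8) & (f <= 30)])
        var_welch = np.var(welch_vals)
        var_perio = np.mean(np.var(np.array(perio_vals), axis=0))
        assert var_welch < var_perio


class TestBandMean:
    def test_flat_density_returns_level(self):
        from betarebound.erp_psd import PSDEstimate

        est = PSDEstimate("Cz", np.linspace(0, 250, 126),
                          np.full(126, 3.0), 0.5, 0.5)
        bm = band_mean(est, (8.0, 30.0))
        assert bm["linear_uv2_per_hz"] == pytest.approx(3.0)
        assert bm["db_per_hz"] == pytest.approx(10 * np.log10(3.0))

    def test_band_outside_signal_content_is_negligible(self):
        t = np.arange(int(20 * FS)) / FS
        est = welch(np.sin(2 * np.pi * 20 * t), FS)
        inside = band_mean(est, (16.0, 24.0))["linear_uv2_per_hz"]
        outside = band_mean(est, (100.0, 200.0))["linear_uv2_per_hz"]
        assert outside < 1e-6 * inside

    def test_empty_band_rejected(self):
        t = np.arange(int(5 * FS)) / FS
        est = welch(np.sin(2 * np.pi * 20 * t), FS)
        with pytest.raises(ValueError, match="band"):
            band_mean(est, (30.5, 31.5))  # between the 2 Hz-spaced bins

    def test_rebound_raises_band_mean_for_weighted_channels(self):
        # paired seeded comparison: same seed with and without a rebound
        sched = br.build_schedule("MIVH", 120, 0, 10, "IDLE")
        base = br.SynthesisParams(seed=55, ers_gain=1.0, erd_gain=1.0,
                                  spurious_rate=0.0)
        boosted = br.SynthesisParams(seed=55, ers_gain=6.0, erd_gain=1.0,
                                     spurious_rate=0.0)
        rec_a, _ = br.generate_session(sched, base)
        rec_b, _ = br.generate_session(sched, boosted)
        for ch in ("Cz", "C1", "C2"):
            est_a = welch(_active_concat(rec_a, sched, ch), FS)
            est_b = welch(_active_concat(rec_b, sched, ch), FS)
            assert (band_mean(est_b)["linear_uv2_per_hz"]
                    > band_mean(est_a)["linear_uv2_per_hz"])


def _active_concat(rec, sched, ch):
    x = rec.channel(ch)
    return np.concatenate(
        [x[int(w0 * FS):int(w1 * FS)] for (w0, w1) in br.active_windows(sched)]
    )
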