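"""OKN preprocessing, slow-phase velocity, switch detection, and duration
summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from okninfo import syndata
from okninfo.okn import (
    DelayResult,
    OculomotorTrace,
    SlowPhaseVelocity,
    SwitchEvent,
    detect_switches,
    estimate_event_kernels,
    fit_gamma,
    interpolate_blinks,
    lowpass_filter,
    okn_report_delay,
    paired_delay_ttest,
    remove_event_responses,
    slow_phase_pipeline,
    slow_phase_velocity,
    to_percent_signal_change,
)


def _ramp_trace(n=5000, rate=500.0, slope=1.0):
    return OculomotorTrace(samples=slope * np.arange(n) / rate, rate=rate)


class TestInterpolateBlinks:
    def test_linear_signal_restored_exactly(self):
        tr = _ramp_trace()
        gap = tr.samples.copy()
        gap[2000:2150] = np.nan
        broken = OculomotorTrace(samples=gap, rate=500.0, blink_events=[(4.0, 4.3)])
        out = interpolate_blinks(broken)
        np.testing.assert_allclose(out.samples, tr.samples, atol=1e-9)

    def test_no_blinks_identity(self):
        tr = _ramp_trace()
        out = interpolate_blinks(tr)
        np.testing.assert_array_equal(out.samples, tr.samples)

    def test_rewritten_sample_count(self):
        # 200 ms blink + 150 ms pad each side = 500 ms = 250 samples at 500 Hz
        t = np.arange(5000) / 500.0
        noisy = np.sin(2 * np.pi * 0.7 * t) + 1000.0  # curved, so interpolation differs
        noisy[500:600] = np.nan
        broken = OculomotorTrace(samples=noisy, rate=500.0, blink_events=[(1.0, 1.2)])
        out = interpolate_blinks(broken, pad=150.0)
        rewritten = np.sum(~np.isclose(out.samples, noisy, rtol=0.0, atol=1e-7, equal_nan=False))
        assert rewritten == int(0.5 * 500)

    def test_boundary_blink_warns_and_fills(self):
        x = np.ones(1000)
        x[:100] = np.nan
        tr = OculomotorTrace(samples=x, rate=500.0, blink_events=[(0.0, 0.2)])
        with pytest.warns(UserWarning, match="boundary"):
            out = interpolate_blinks(tr)
        assert not np.isnan(out.samples).any()


class TestLowpassFilter:
    def test_dc_preserved(self):
        tr = OculomotorTrace(samples=np.full(4000, 3.7), rate=500.0)
        out = lowpass_filter(tr)
        np.testing.assert_allclose(out.samples, 3.7, rtol=1e-6)

    @pytest.mark.parametrize(
        "freq,max_gain",
        [
            # zero-phase 3rd-order Butterworth: |H|^2 = 1/(1+(f/10)^6)
            (50.0, 1.0 / (1 + 5.0**6)),
            (1.0, 1.0),
        ],
    )
    def test_sinusoid_attenuation_matches_response(self, freq, max_gain):
        t = np.arange(10_000) / 500.0
        tr = OculomotorTrace(samples=np.sin(2 * np.pi * freq * t), rate=500.0)
        out = lowpass_filter(tr)
        amp = np.abs(out.samples[2000:-2000]).max()
        if freq == 50.0:
            assert amp < 0.01  # < 1% of input
        else:
            assert amp > 0.99 * max_gain

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(_ramp_trace(), cutoff=250.0)


class TestDeconvolution:
    rate = 100.0

    def _make(self, onsets, seed=0, n=12000):
        rng = np.random.default_rng(seed)
        kernel = np.exp(-np.arange(100) / 20.0) * np.sin(np.arange(100) / 6.0)
        x = rng.normal(0, 0.3, n)
        for on in onsets:
            i = int(on * self.rate)
            x[i : i + 100] += kernel[: max(n - i, 0)]
        tr = OculomotorTrace(samples=x, rate=self.rate)
        return tr, kernel, rng

    def test_no_events_identity(self):
        tr = _ramp_trace()
        out = remove_event_responses(tr, [], [])
        np.testing.assert_array_equal(out.samples, tr.samples)

    @pytest.mark.parametrize("spacing", [4.0, 0.6])  # well-separated and overlapping
    def test_kernel_recovery(self, spacing):
        # jittered onsets: perfectly periodic overlapping events make the
        # kernel identifiable only up to a shifted combination
        jitter = np.random.default_rng(1).uniform(-0.2, 0.2, size=200)
        onsets = list(np.arange(2.0, 110.0, spacing) + jitter[: len(np.arange(2.0, 110.0, spacing))])
        tr, kernel, rng = self._make(onsets)
        events = [(on, on + 0.05) for on in onsets]
        kernels = estimate_event_kernels(tr, blink_events=events, window=(0.0, 1.0))
        rec = kernels["blink"]
        r = np.corrcoef(rec, kernel)[0, 1]
        assert r > 0.95
        out = remove_event_responses(tr, blink_events=events, window=(0.0, 1.0))
        assert out.samples.var() < 1.5 * 0.3**2  # residual ~ noise variance

    def test_window_longer_than_trace_rejected(self):
        tr = _ramp_trace(n=100)
        with pytest.raises(ValueError):
            remove_event_responses(tr, blink_events=[(0.1, 0.2)], window=(0.0, 10.0))


class TestPercentSignalChange:
    def test_constant_trace_all_zeros(self):
        tr = OculomotorTrace(samples=np.full(100, 5.0), rate=500.0)
        out = to_percent_signal_change(tr)
        np.testing.assert_allclose(out.samples, 0.0)

    def test_definition_and_centering(self):
        tr = OculomotorTrace(samples=np.array([1.1, 0.9]), rate=500.0)
        out = to_percent_signal_change(tr, block_mean=1.0)
        np.testing.assert_allclose(out.samples, [10.0, -10.0])
        assert abs(out.samples.mean()) < 1e-9

    def test_zero_mean_rejected(self):
        tr = OculomotorTrace(samples=np.array([1.0, -1.0]), rate=500.0)
        with pytest.raises(ValueError):
            to_percent_signal_change(tr)


class TestSlowPhaseVelocity:
    def test_ramp_gives_constant_velocity(self):
        a = 2.5
        tr = _ramp_trace(slope=a)
        vel = slow_phase_velocity(tr)
        interior = vel.values[500:-500]
        np.testing.assert_allclose(interior, a * 0.002, rtol=1e-6)

    def test_linearity_sign_flip(self):
        tr = _ramp_trace()
        flipped = OculomotorTrace(samples=-tr.samples, rate=tr.rate)
        v1 = slow_phase_velocity(tr)
        v2 = slow_phase_velocity(flipped)
        np.testing.assert_allclose(v2.values, -v1.values, atol=1e-12)

    def test_sinusoid_zero_crossings_at_extrema(self):
        t = np.arange(5000) / 500.0
        tr = OculomotorTrace(samples=np.sin(2 * np.pi * t / 2.0), rate=500.0)
        vel = slow_phase_velocity(tr)
        v = vel.values[300:-300]
        crossings = (np.where(np.diff(np.sign(v)) != 0)[0] + 300) / 500.0
        extrema = np.arange(0.5, 9.6, 1.0)
        for c in crossings:
            assert np.min(np.abs(extrema - c)) <= 1.5 / 500.0

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            slow_phase_velocity(OculomotorTrace(samples=np.zeros(10), rate=500.0))


class TestDetectSwitches:
    def test_sine_crossings_and_alternation(self):
        t = np.arange(5000) / 500.0
        vel = SlowPhaseVelocity(values=np.sin(2 * np.pi * t / 2.0), rate=500.0)
        ev = detect_switches(vel, hysteresis=0.0)
        times = [e.time for e in ev]
        np.testing.assert_allclose(times, np.arange(1.0, 9.1, 1.0), atol=2 / 500.0)
        dirs = [e.direction for e in ev]
        assert all(a != b for a, b in zip(dirs, dirs[1:]))
        # negative-to-positive maps to to_DIF with the default polarity
        assert dirs[0] == "to_INT"  # sin goes positive->negative at t=1

    def test_all_zero_velocity_warns_empty(self):
        vel = SlowPhaseVelocity(values=np.zeros(1000), rate=500.0)
        with pytest.warns(UserWarning):
            assert detect_switches(vel) == []

    def test_subthreshold_chatter_suppressed(self):
        rng = np.random.default_rng(0)
        v = 0.5 * np.ones(5000)
        v[2000:2100] = -1e-4 + 1e-5 * rng.normal(size=100)  # tiny dip below zero
        vel = SlowPhaseVelocity(values=v, rate=500.0)
        ev = detect_switches(vel, hysteresis=0.01)
        assert ev == []

    def test_polarity_flag(self):
        t = np.arange(3000) / 500.0
        vel = SlowPhaseVelocity(values=np.sin(2 * np.pi * t / 2.0), rate=500.0)
        ev = detect_switches(vel, hysteresis=0.0, positive_to="to_INT")
        assert ev[0].direction == "to_DIF"


class TestPipelineProperties:
    def test_idempotence_on_clean_trace(self):
        t = np.arange(20_000) / 500.0
        clean = OculomotorTrace(samples=np.sin(2 * np.pi * 0.2 * t), rate=500.0)
        out = lowpass_filter(interpolate_blinks(clean))
        rms_in = np.sqrt(np.mean(clean.samples[1000:-1000] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[1000:-1000] ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.01

    def test_detection_recall_on_clean_session(self, clean_session):
        vel = slow_phase_pipeline(clean_session.okn)
        ev = detect_switches(vel)
        true_t = np.array([e.time for e in clean_session.switch_events])
        det_t = np.array([e.time for e in ev])
        recall = np.mean([np.min(np.abs(det_t - t)) <= 0.1 for t in true_t])
        assert recall >= 0.9
        dirs = [e.direction for e in ev]
        assert all(a != b for a, b in zip(dirs, dirs[1:]))

    def test_recall_degrades_with_noise(self):
        recalls = []
        for noise in (0.03, 0.5, 2.0):
            cfg = syndata.SimConfig(seed=21, okn_noise_sd=noise)
            s = syndata.simulate_session(cfg, session_length=120.0)
            vel = slow_phase_pipeline(s.okn)
            det_t = np.array([e.time for e in detect_switches(vel)])
            true_t = np.array([e.time for e in s.switch_events])
            if det_t.size == 0:
                recalls.append(0.0)
                continue
            recalls.append(np.mean([np.min(np.abs(det_t - t)) <= 0.1 for t in true_t]))
        assert recalls[0] >= recalls[1] >= recalls[2]


class TestGammaFit:
    def test_parameter_recovery(self):
        d = sps.gamma.rvs(3.0, scale=1.5, size=2000, random_state=1)
        shape, scale, p = fit_gamma(d)
        assert abs(shape - 3.0) / 3.0 < 0.1
        assert abs(scale - 1.5) / 1.5 < 0.1
        assert p > 0.01

    def test_exponential_data_shape_one(self):
        d = sps.expon.rvs(scale=2.0, size=2000, random_state=2)
        shape, _, _ = fit_gamma(d)
        assert abs(shape - 1.0) < 0.1

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma(np.full(100, 2.0))
        with pytest.raises(ValueError):
            fit_gamma(np.array([-1.0] * 30))


class TestReportDelay:
    def _ev(self, times, dirs, source):
        return [SwitchEvent(t, d, source) for t, d in zip(times, dirs)]

    def test_simple_pairing(self):
        okn_ev = self._ev([1.0, 5.0], ["to_INT", "to_DIF"], "okn_crossing")
        btn = self._ev([1.4, 5.6], ["to_INT", "to_DIF"], "button")
        res = okn_report_delay(okn_ev, btn)
        assert res.delays["to_INT"] == pytest.approx([0.4])
        assert res.delays["to_DIF"] == pytest.approx([0.6])
        assert res.n_unpaired == 0

    def test_unpaired_press_counted(self):
        okn_ev = self._ev([1.0], ["to_INT"], "okn_crossing")
        btn = self._ev([9.0], ["to_INT"], "button")
        res = okn_report_delay(okn_ev, btn, max_pairing=2.0)
        assert res.n_unpaired == 1
        assert res.delays["to_INT"] == []

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            okn_report_delay([], [])

    def test_delay_difference_power(self):
        """INT delays N(0.5, 0.1) vs DIF N(0.4, 0.1), 40 subjects x 50
        switches: the paired t-test detects INT > DIF in > 90% of 100
        simulations."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            results = []
            for _s in range(40):
                results.append(
                    DelayResult(
                        delays={
                            "to_INT": rng.normal(0.5, 0.1, 50).tolist(),
                            "to_DIF": rng.normal(0.4, 0.1, 50).tolist(),
                        },
                        n_unpaired=0,
                    )
                )
            t, p = paired_delay_ttest(results)
            hits += (t > 0) and (p < 0.05)
        assert hits > 90
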