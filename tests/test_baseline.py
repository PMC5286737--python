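"""Susceptibility model, drift estimation, unwrapping and temporal filter."""

import warnings

import numpy as np
import pytest
from scipy.ndimage import binary_erosion
from scipy.signal import freqz

import cardiotherm as ct
from cardiotherm.baseline import (
    TemporalUnwrapper,
    correct_susceptibility,
    estimate_drift,
    learn_phase_model,
    lowpass_step,
    make_filter,
)
from cardiotherm.phantom import default_gain_map


class TestLearnPhaseModel:
    def test_constant_phases(self):
        rng = np.random.default_rng(0)
        phases = np.broadcast_to(rng.normal(size=(6, 6)), (20, 6, 6)).copy()
        coeffs = rng.normal(size=(20, 2))
        model = learn_phase_model(phases, coeffs)
        np.testing.assert_allclose(model.coefficient_maps, 0.0, atol=1e-10)
        np.testing.assert_allclose(model.intercept_map, phases[0], atol=1e-10)

    def test_recovers_gain_map(self):
        """phi = g(x) * d(t) with coefficients proportional to d(t)."""
        gain = default_gain_map((24, 24))
        d = 5.0 * np.sin(2 * np.pi * 0.4 * np.arange(30))
        phases = gain[None] * d[:, None, None] + 0.3
        model = learn_phase_model(phases, d[:, None])
        g = model.coefficient_maps[0].ravel()
        corr = np.corrcoef(g, gain.ravel())[0, 1]
        assert corr >= 0.99
        np.testing.assert_allclose(model.intercept_map, 0.3, atol=1e-8)

    def test_default_learning_window_is_30(self):
        assert ct.PipelineConfig().n_learn == 30

    def test_rank_deficient_falls_back(self):
        phases = np.zeros((10, 4, 4))
        coeffs = np.ones((10, 2))  # constant -> collinear with intercept
        with pytest.warns(RuntimeWarning):
            model = learn_phase_model(phases, coeffs)
        np.testing.assert_array_equal(model.coefficient_maps, 0.0)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            learn_phase_model(np.zeros((3, 4, 4)), np.zeros((3, 2)))


class TestCorrectSusceptibility:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(1)
        phases = rng.normal(size=(15, 6, 6))
        coeffs = rng.normal(size=(15, 2))
        return learn_phase_model(phases, coeffs)

    def test_zero_coefficients_identity(self, model):
        phase = np.random.default_rng(2).normal(size=(6, 6))
        np.testing.assert_array_equal(
            correct_susceptibility(phase, np.zeros(2), model), phase
        )

    def test_linear_not_idempotent(self, model):
        phase = np.zeros((6, 6))
        c = np.array([1.0, -0.5])
        once = correct_susceptibility(phase, c, model)
        twice = correct_susceptibility(once, c, model)
        np.testing.assert_allclose(twice, 2 * once, atol=1e-12)

    def test_coefficient_count_mismatch(self, model):
        with pytest.raises(ValueError):
            correct_susceptibility(np.zeros((6, 6)), np.zeros(3), model)

    def test_phantom_variance_reduction(self):
        """At the design conditions (5 mm breathing, default gain, SNR 100)
        the learned model removes >= 80% of the temporal phase variance."""
        from cardiotherm import registration as reg

        cfg = ct.PhantomConfig(
            grid_size=(64, 64), n_frames=70, heat_peak_degc=0.0,
            drift_rate_rad_s=0.0, resp_amplitude_mm=5.0, snr=100.0, seed=4,
        )
        series, gt = ct.generate_series(cfg)
        flows = [reg.estimate_flow(series.magnitude[i], series.magnitude[0])
                 for i in range(cfg.n_frames)]
        basis = reg.build_motion_basis(flows[:30], 2)
        coeffs = np.stack([reg.project_motion(f, basis) for f in flows])
        unw = TemporalUnwrapper()
        phis = np.stack([unw.update(reg.warp_phase(series.phase[i], flows[i]))
                         for i in range(cfg.n_frames)])
        model = learn_phase_model(phis[:30], coeffs[:30])
        post = phis[30:]
        corrected = np.stack([
            correct_susceptibility(post[j], coeffs[30 + j], model)
            for j in range(post.shape[0])
        ])
        roi = binary_erosion(gt.body_mask, iterations=6)
        reduction = 1 - corrected.var(axis=0)[roi].mean() / post.var(axis=0)[roi].mean()
        assert reduction >= 0.80


class TestEstimateDrift:
    def test_constant_offset(self):
        diff = np.full((10, 10), 0.37)
        assert estimate_drift(diff, np.ones((10, 10), bool)) == pytest.approx(0.37)

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            estimate_drift(np.zeros((4, 4)), np.zeros((4, 4), bool))

    def test_recovers_phantom_drift_rate(self):
        cfg = ct.PhantomConfig(
            grid_size=(48, 48), n_frames=40, heat_peak_degc=0.0,
            heat_onset_frame=0, heat_duration_frames=0,
            resp_amplitude_mm=0.0, drift_rate_rad_s=-0.00226, snr=80.0, seed=6,
        )
        series, gt = ct.generate_series(cfg)
        mask = binary_erosion(gt.body_mask, iterations=4)
        t_idx = 35
        diff = np.angle(np.exp(1j * (series.phase[t_idx] - series.phase[0])))
        est = estimate_drift(diff, mask)
        true = cfg.drift_rate_rad_s * series.timestamps[t_idx]
        # phase noise ~ 1/snr; median efficiency absorbed by the 3x margin
        tol = 3 * (1 / cfg.snr) / np.sqrt(mask.sum())
        assert est == pytest.approx(true, abs=max(tol, 3e-3))

    def test_five_degree_drift_fully_removed(self):
        """A drift worth ~5 degC over 150 s must leave |mu_T| < 0.3 degC."""
        k = ct.PRFSParams().k
        cfg = ct.PhantomConfig(
            grid_size=(48, 48), n_frames=180, heat_peak_degc=0.0,
            resp_amplitude_mm=0.0, drift_rate_rad_s=5.0 / (k * 150.0),
            snr=100.0, seed=7,
        )
        series, gt = ct.generate_series(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = ct.run_pipeline(
                series,
                ct.PipelineConfig(rf_start_frame=None, drift_mask=gt.body_mask),
            )
        roi = binary_erosion(gt.body_mask, iterations=4)
        mu = res.temperature.dT[30:].mean(axis=0)
        assert abs(mu[roi].mean()) < 0.3


class TestLowpassFilter:
    def test_constant_input_reproduced(self):
        state = make_filter(sampling_hz=1.0)
        frame = np.full((4, 4), 3.3)
        for _ in range(5):
            state, out = lowpass_step(state, frame)
            np.testing.assert_allclose(out, 3.3, atol=1e-10)

    def test_white_noise_variance_reduction(self):
        """Output variance ratio equals the filter's noise-equivalent
        bandwidth fraction (transfer-function integral oracle)."""
        state = make_filter(cutoff_hz=0.14, sampling_hz=1.0)
        w, h = freqz(state.b, state.a, worN=20000)
        neb_ratio = np.trapezoid(np.abs(h) ** 2, w) / np.pi
        rng = np.random.default_rng(8)
        x = rng.normal(size=(4000, 8, 8))
        outs = []
        started = False
        for frame in x:
            state, y = lowpass_step(state, frame)
            outs.append(y)
        out = np.stack(outs[500:])  # discard warm-up
        ratio = out.var() / x.var()
        assert ratio == pytest.approx(neb_ratio, rel=0.15)

    def test_step_response_matches_batch_filter(self):
        """Streaming updates reproduce the closed-form (batch lfilter) step
        response; the discrete order-2 Butterworth rings by only a few
        percent and settles to the step value."""
        from scipy.signal import lfilter

        state = make_filter(cutoff_hz=0.14, sampling_hz=1.0)
        x = np.concatenate([np.zeros(1), np.ones(80)])
        zi = state.zi_unit * 0.0  # batch oracle, warm-started at x[0] = 0
        expected, _ = lfilter(state.b, state.a, x, zi=zi)
        ys = []
        for v in x:
            state, y = lowpass_step(state, np.full((2, 2), v))
            ys.append(y[0, 0])
        np.testing.assert_allclose(ys, expected, atol=1e-12)
        # under-damped discrete pair: bounded ringing, no large overshoot
        assert max(ys) <= 1.10
        assert ys[-1] == pytest.approx(1.0, abs=1e-3)

    def test_linearity(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(30, 3, 3))
        b = rng.normal(size=(30, 3, 3))
        sa, sb, sab = make_filter(), make_filter(), make_filter()
        for i in range(30):
            sa, ya = lowpass_step(sa, a[i])
            sb, yb = lowpass_step(sb, b[i])
            sab, yab = lowpass_step(sab, a[i] + b[i])
            np.testing.assert_allclose(yab, ya + yb, atol=1e-10)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_filter(cutoff_hz=0.6, sampling_hz=1.0)


class TestTemporalUnwrapper:
    def test_tracks_large_cumulative_excursion(self):
        # 6 rad total in 0.3 rad steps: wrapped input, unwrapped output
        true = np.linspace(0, 6.0, 21)
        unw = TemporalUnwrapper()
        out = [unw.update(np.angle(np.exp(1j * np.full((2, 2), v))))[0, 0]
               for v in true]
        np.testing.assert_allclose(out, true, atol=1e-9)

    def test_exact_when_increment_below_pi(self):
        rng = np.random.default_rng(10)
        steps = rng.uniform(-3.0, 3.0, size=40)
        true = np.cumsum(steps)
        unw = TemporalUnwrapper()
        out = [unw.update(np.angle(np.exp(1j * np.full((1, 1), v))))[0, 0]
               for v in true]
        # first sample anchors at the wrapped value; differences are exact
        np.testing.assert_allclose(np.diff(out), np.diff(true), atol=1e-9)
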