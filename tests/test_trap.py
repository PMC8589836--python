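"""Worm-like chain conversion, tether screening, velocities and pauses."""

import numpy as np
import pytest

from motorlab import synth, trap


def _clean_params(**kw):
    defaults = dict(pause_rate_per_kb=0.0)
    defaults.update(kw)
    return synth.TrapSimParams(**defaults)


class TestWLC:
    def test_relative_extension_at_five_piconewton(self, wlc):
        assert trap.wlc_relative_extension(5.0, wlc) == pytest.approx(0.9409, abs=1e-4)

    def test_contour_extension_at_five_piconewton(self, wlc):
        ext = wlc.contour_length_nm * trap.wlc_relative_extension(5.0, wlc)
        assert ext == pytest.approx(1087.7, abs=0.1)

    def test_monotone_in_force(self, wlc):
        forces = np.linspace(0.5, 60, 200)
        assert np.all(np.diff(trap.wlc_relative_extension(forces, wlc)) > 0)

    def test_infinite_stretch_modulus_reduces_to_inextensible(self, wlc):
        stiff = trap.WLCParams(stretch_modulus_pN=1e12)
        expected = 1 - 0.5 * np.sqrt(wlc.thermal_energy_pN_nm / (5.0 * 50.0))
        assert trap.wlc_relative_extension(5.0, stiff) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_force_raises(self, wlc):
        with pytest.raises(ValueError):
            trap.wlc_relative_extension(0.0, wlc)

    def test_inversion_round_trips(self, wlc):
        """bp -> extension -> bp is exact over the working force range."""
        bp = np.array([1.0, 340.0, 1700.0, 3400.0])
        for force in np.linspace(1.0, 60.0, 30):
            back = trap.bp_from_extension(trap.extension_from_bp(bp, force, wlc), force, wlc)
            assert np.allclose(back, bp, rtol=1e-9)

    def test_zero_extension_and_linearity(self, wlc):
        assert trap.bp_from_extension(0.0, 5.0, wlc) == 0.0
        one = trap.bp_from_extension(500.0, 5.0, wlc)
        assert trap.bp_from_extension(250.0, 5.0, wlc) == pytest.approx(one / 2)


class TestScreenTether:
    @staticmethod
    def _curve(wlc, offset=0.0, scale=1.0, noise=0.0, seed=0):
        forces = np.linspace(1.0, 10.0, 40)
        ext = scale * wlc.contour_length_nm * trap.wlc_relative_extension(forces, wlc) + offset
        if noise:
            ext = ext + np.random.default_rng(seed).normal(0, noise, forces.size)
        return forces, ext

    def test_injected_offset_recovered(self, wlc):
        forces, ext = self._curve(wlc, offset=-50.0, noise=2.0)
        res = trap.screen_tether(forces, ext, wlc)
        assert res.accepted
        assert res.offset_nm == pytest.approx(-50.0, abs=5.0)

    def test_offset_outside_window_rejected(self, wlc):
        forces, ext = self._curve(wlc, offset=-150.0)
        res = trap.screen_tether(forces, ext, wlc)
        assert not res.accepted and "offset_outside_window" in res.reject_reasons

    def test_wrong_contour_length_rejected_by_residuals(self, wlc):
        forces, ext = self._curve(wlc, scale=0.5)
        res = trap.screen_tether(forces, ext, wlc)
        assert not res.accepted
        assert {"residual_extremum", "residual_variance"} & set(res.reject_reasons)

    def test_bad_force_grids_raise(self, wlc):
        with pytest.raises(ValueError):
            trap.screen_tether(np.array([5.0, 3.0, 8.0]), np.zeros(3), wlc)
        with pytest.raises(ValueError):
            trap.screen_tether(np.array([5.0, 6.0]), np.zeros(2), wlc)  # < 2 pN span


class TestRollingVelocity:
    def test_linear_packaging_gives_constant_velocity(self, wlc):
        trace, _ = synth.gen_extension_trace(_clean_params(noise_sd_nm=0.0), wlc, seed=50)
        v = trap.rolling_velocity(trace.with_bp(wlc))
        assert np.allclose(v[100:-100], 960.0, rtol=1e-6)

    def test_white_noise_has_zero_mean_velocity(self, wlc, rng):
        times = np.arange(0, 10, 0.001)
        ext = trap.ExtensionTrace(times, rng.normal(1000, 2, times.size), 5.0).with_bp(wlc)
        v = trap.rolling_velocity(ext)
        se = v.std() / np.sqrt(v.size / 100)  # ~window-length correlation
        assert abs(v.mean()) < 3 * se + 1.0

    def test_window_too_small_raises(self, wlc):
        trace, _ = synth.gen_extension_trace(_clean_params(), wlc, seed=51)
        with pytest.raises(ValueError):
            trap.rolling_velocity(trace.with_bp(wlc), window_s=0.001)

    def test_trace_shorter_than_window_raises(self, wlc):
        tr = trap.ExtensionTrace(np.arange(0, 0.05, 0.001), np.zeros(50), 5.0)
        tr = trap.ExtensionTrace(tr.times, tr.extension_nm, 5.0, np.zeros(50))
        with pytest.raises(ValueError):
            trap.rolling_velocity(tr, window_s=1.0)


class TestPauseDetection:
    def test_two_injected_plateaus_recovered(self, wlc):
        rng = np.random.default_rng(52)
        for _ in range(10):
            trace, truth = synth.gen_extension_trace(
                _clean_params(), wlc, seed=rng,
                pauses=[(1000.0, 0.5, "plateau"), (2200.0, 0.5, "plateau")],
            )
            tr = trace.with_bp(wlc)
            ann = trap.detect_pauses(trap.rolling_velocity(tr), tr.times)
            assert ann.n_pauses == 2
            for (ds, de), (ts, te) in zip(ann.intervals, truth.pauses.intervals):
                assert abs(ds - ts) <= 0.1 and abs(de - te) <= 0.1
            assert all(t is trap.PauseType.PLATEAU for t in ann.pause_types)

    def test_brief_interruption_not_reported(self, wlc):
        """A 0.05-s interruption is below the >0.1-s pause rule."""
        trace, _ = synth.gen_extension_trace(
            _clean_params(), wlc, seed=53, pauses=[(1500.0, 0.05, "plateau")]
        )
        tr = trace.with_bp(wlc)
        ann = trap.detect_pauses(trap.rolling_velocity(tr), tr.times)
        assert ann.n_pauses == 0

    def test_unpackaging_pause_classified(self, wlc):
        trace, _ = synth.gen_extension_trace(
            _clean_params(), wlc, seed=54, pauses=[(1200.0, 0.8, "unpackaging")]
        )
        tr = trace.with_bp(wlc)
        ann = trap.detect_pauses(trap.rolling_velocity(tr), tr.times)
        assert ann.n_pauses == 1
        assert ann.pause_types[0] is trap.PauseType.UNPACKAGING
        assert -500.0 < ann.pause_velocities_bp_s[0] < -100.0

    def test_false_positive_rate(self, wlc):
        rng = np.random.default_rng(55)
        fp = 0
        for _ in range(50):
            trace, _ = synth.gen_extension_trace(_clean_params(), wlc, seed=rng)
            tr = trace.with_bp(wlc)
            fp += trap.detect_pauses(trap.rolling_velocity(tr), tr.times).n_pauses
        assert fp / 50 <= 0.1

    def test_classify_pause_conventions(self):
        assert trap.classify_pause(0.0) is trap.PauseType.PLATEAU
        assert trap.classify_pause(-300.0) is trap.PauseType.UNPACKAGING
        assert trap.classify_pause(-20.0, plateau_band_bp_s=50.0) is trap.PauseType.PLATEAU
        with pytest.warns(RuntimeWarning):
            assert trap.classify_pause(120.0) is trap.PauseType.PLATEAU


class TestTraceMetrics:
    def test_pause_frequency_arithmetic(self, wlc):
        """Three pauses over 2.5 kb packaged give 1.2 pauses per kb."""
        params = _clean_params(dna_length_bp=2500.0)
        trace, truth = synth.gen_extension_trace(
            params, wlc, seed=56,
            pauses=[(500.0, 0.4, "plateau"), (1200.0, 0.4, "plateau"), (2000.0, 0.4, "plateau")],
        )
        tr = trace.with_bp(wlc)
        v = trap.rolling_velocity(tr)
        # arithmetic on exact (ground-truth) pause intervals
        m = trap.trace_metrics(tr, truth.pauses, velocity_bp_s=v)
        assert m.n_pauses == 3
        assert m.pause_frequency_per_kb == pytest.approx(1.2, rel=0.02)
        # detected pauses give the same frequency within detection smear
        m_det = trap.trace_metrics(tr, trap.detect_pauses(v, tr.times), velocity_bp_s=v)
        assert m_det.pause_frequency_per_kb == pytest.approx(1.2, rel=0.15)

    def test_velocity_recovery_across_observed_range(self, wlc):
        """Median pause-free velocity error < 5% over 100-2000 bp/s."""
        rng = np.random.default_rng(57)
        errors = []
        while len(errors) < 200:
            v_true = float(rng.uniform(100, 2000))
            params = synth.TrapSimParams(pause_free_velocity_bp_s=v_true, pause_rate_per_kb=1.2)
            trace, truth = synth.gen_extension_trace(params, wlc, seed=rng)
            if truth.failure:
                continue
            tr = trace.with_bp(wlc)
            v = trap.rolling_velocity(tr)
            ann = trap.detect_pauses(v, tr.times)
            m = trap.trace_metrics(tr, ann, velocity_bp_s=v)
            errors.append(abs(m.pause_free_velocity_bp_s - v_true) / v_true)
        assert np.median(errors) < 0.05

    def test_zero_pauses_metrics(self, wlc):
        trace, _ = synth.gen_extension_trace(_clean_params(), wlc, seed=58)
        tr = trace.with_bp(wlc)
        v = trap.rolling_velocity(tr)
        m = trap.trace_metrics(tr, trap.detect_pauses(v, tr.times), velocity_bp_s=v)
        assert m.pause_frequency_per_kb == 0.0
        assert m.mean_pause_duration_s is None

    def test_start_time_from_atp_entry(self, wlc):
        params = _clean_params(start_delay_s=2.0)
        trace, _ = synth.gen_extension_trace(params, wlc, seed=59)
        tr = trace.with_bp(wlc)
        v = trap.rolling_velocity(tr)
        ann = trap.detect_pauses(v, tr.times)
        m = trap.trace_metrics(tr, ann, t0_atp_entry=0.0, velocity_bp_s=v)
        assert m.start_time_s == pytest.approx(2.0, abs=0.1)

    def test_pause_plus_packaging_time_conserved(self, wlc):
        trace, _ = synth.gen_extension_trace(
            _clean_params(), wlc, seed=60, pauses=[(1000.0, 0.6, "plateau")]
        )
        tr = trace.with_bp(wlc)
        v = trap.rolling_velocity(tr)
        ann = trap.detect_pauses(v, tr.times)
        total_pause = sum(ann.durations)
        m = trap.trace_metrics(tr, ann, velocity_bp_s=v)
        packaging_time = m.total_packaged_bp / m.pause_free_velocity_bp_s
        duration = tr.times[-1] - m.start_time_s
        assert packaging_time + total_pause == pytest.approx(duration, abs=0.05)

    def test_flat_trace_metrics_undefined(self, wlc):
        times = np.arange(0, 5, 0.001)
        tr = trap.ExtensionTrace(times, np.full(times.size, 800.0), 5.0).with_bp(wlc)
        v = trap.rolling_velocity(tr)
        with pytest.raises(trap.MetricsUndefinedError):
            trap.trace_metrics(tr, trap.PauseAnnotation(), velocity_bp_s=v)
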