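"""Trace metrics: dF extraction, filtering, bleach correction, curves."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vcfkit import (
    AbsorbanceReading,
    VcfTrace,
    attenuation_fraction,
    boxcar_filter,
    compute_delta_f,
    fit_fast_component,
    fv_curve,
    gv_curve,
    photobleach_correct,
)


def make_trace(F, dt=0.5, V=None, I=None, **meta):
    F = np.asarray(F, dtype=float)
    t = np.arange(len(F)) * dt
    if V is None:
        V = np.full_like(t, -60.0)
    return VcfTrace(t=t, F=F, V=np.asarray(V, dtype=float), I=I, meta=meta)


class TestBoxcar:
    def test_single_point_is_identity(self):
        tr = make_trace([1.0, 5.0, 2.0])
        assert boxcar_filter(tr, 1) is tr

    def test_constant_trace_unchanged(self):
        tr = make_trace(np.full(50, 3.3))
        assert np.allclose(boxcar_filter(tr, 3).F, 3.3)

    def test_three_point_average(self):
        tr = make_trace([0.0, 3.0, 0.0])
        out = boxcar_filter(tr, 3)
        assert out.F[1] == pytest.approx(1.0)
        # shrunken edge windows
        assert out.F[0] == pytest.approx(1.5)
        assert out.F[2] == pytest.approx(1.5)

    def test_even_points_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            boxcar_filter(make_trace([1.0, 2.0, 3.0]), 2)

    def test_interior_mean_preserved(self, rng):
        F = rng.normal(size=200)
        out = boxcar_filter(make_trace(F), 5)
        # away from the edges a moving average redistributes but preserves mass
        assert np.mean(out.F[2:-2]) == pytest.approx(
            np.mean([np.mean(F[i - 2 : i + 3]) for i in range(2, 198)]), rel=1e-12
        )


class TestPhotobleach:
    def test_flat_baseline_leaves_trace_unchanged(self, rng):
        base = make_trace(np.full(400, 50.0) + rng.normal(0, 1e-4, 400))
        tr = make_trace(50.0 + np.sin(np.arange(400) / 40.0))
        corrected, info = photobleach_correct(tr, base)
        assert np.max(np.abs(corrected.F - tr.F)) < 1e-2
        assert abs(info.B) < 0.05

    def test_pure_bleach_trace_corrects_to_constant(self):
        t = np.arange(2000) * 0.5
        bleach = 100.0 * (0.95 + 0.05 * np.exp(-t / 20000.0))
        base = make_trace(bleach)
        corrected, info = photobleach_correct(base, base)
        assert np.max(np.abs(corrected.F - corrected.F[0])) < 1e-6
        assert info.tau_b_ms == pytest.approx(20000.0, rel=1e-3)

    def test_signal_plus_bleach_recovers_signal(self, rng):
        t = np.arange(2400) * 0.5
        signal = 100.0 - 3.0 * np.exp(-((t - 200.0) ** 2) / 5000.0)
        decay = 0.95 + 0.05 * np.exp(-t / 20000.0)
        noise_sd = 0.05
        tr = make_trace(signal * decay + rng.normal(0, noise_sd, len(t)))
        base = make_trace(100.0 * decay + rng.normal(0, noise_sd, len(t)))
        corrected, _ = photobleach_correct(tr, base)
        rms = np.sqrt(np.mean((corrected.F - signal) ** 2))
        assert rms < 3 * noise_sd

    def test_trending_unfittable_baseline_raises(self):
        base = make_trace(np.linspace(100.0, 100.0, 10))
        tr = make_trace(np.full(10, 100.0))
        # flat is fine ...
        photobleach_correct(tr, base)
        # ... but a baseline at a different sampling rate is rejected
        other = make_trace(np.full(10, 100.0), dt=1.0)
        with pytest.raises(ValueError, match="sampling"):
            photobleach_correct(tr, other)


class TestDeltaF:
    def _piecewise_trace(self):
        # F_h = 100; step dips to a 97 plateau, relaxes to a 99 plateau at
        # the step end; post-step dips to 95 before recovering
        dt = 0.5
        pre = np.full(200, 100.0)
        dip = np.full(400, 97.0)
        relax = np.full(400, 99.0)
        tail = np.concatenate([np.full(200, 95.0), np.full(200, 100.0)])
        F = np.concatenate([pre, dip, relax, tail])
        return make_trace(F, dt=dt), (200 * dt, 1000 * dt)

    def test_constant_trace_gives_zero_metrics(self):
        tr = make_trace(np.full(1000, 42.0))
        m = compute_delta_f(tr, (100.0, 400.0))
        assert m.F_h == pytest.approx(42.0)
        for v in (m.dF_peak, m.dF_ss, m.dF_tail, m.dF_hook):
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_piecewise_fixture_values(self):
        tr, window = self._piecewise_trace()
        # unsmoothed extraction: the fixture's plateaus make values exact
        m = compute_delta_f(tr, window, smooth_points=1)
        assert m.F_h == pytest.approx(100.0)
        assert m.dF_peak == pytest.approx(-3.0)
        assert m.dF_ss == pytest.approx(-1.0)
        assert m.dF_tail == pytest.approx(-5.0)
        assert m.dF_hook == pytest.approx(-4.0)
        assert m.dF_peak_pct == pytest.approx(-3.0)
        assert m.dF_ss_pct == pytest.approx(-1.0)
        assert m.dF_tail_pct == pytest.approx(-5.0)
        assert m.dF_hook_pct == pytest.approx(-4.0)

    def test_hook_identity_is_exact(self, rng):
        for _ in range(10):
            F = 100.0 + rng.normal(0, 1.0, 800)
            m = compute_delta_f(make_trace(F), (100.0, 300.0))
            assert m.dF_hook == m.dF_tail - m.dF_ss  # exact, by construction

    def test_window_outside_trace_rejected(self):
        tr = make_trace(np.full(100, 1.0))
        with pytest.raises(ValueError, match="step_window"):
            compute_delta_f(tr, (10.0, 1000.0))
        with pytest.raises(ValueError, match="pre-step"):
            compute_delta_f(tr, (0.0, 40.0))

    def test_nonpositive_baseline_rejected(self):
        tr = make_trace(np.full(200, -5.0))
        with pytest.raises(ValueError, match="F_h"):
            compute_delta_f(tr, (50.0, 90.0))


class TestFvCurve:
    def _metrics(self, values):
        out = []
        for v, dF in values:
            tr = make_trace(
                np.concatenate(
                    [
                        np.full(100, 100.0),
                        np.full(200, 100.0 + dF),
                        np.full(100, 100.0 + 1.5 * dF),
                    ]
                )
            )
            out.append((v, compute_delta_f(tr, (50.0, 150.0), smooth_points=1)))
        return out

    def test_normalization_preserves_sign_and_scales_to_unit_max(self):
        curve = fv_curve(self._metrics([(0.0, -1.0), (50.0, -2.0), (100.0, -4.0)]), "ss")
        assert curve.y == pytest.approx([-0.25, -0.5, -1.0], abs=1e-9)

    def test_every_metric_selectable(self):
        ms = self._metrics([(0.0, -1.0), (100.0, -2.0)])
        for which in ("peak", "ss", "tail", "hook"):
            fv_curve(ms, which)
        with pytest.raises(ValueError, match="selector"):
            fv_curve(ms, "nope")

    def test_all_zero_metrics_rejected(self):
        ms = self._metrics([(0.0, 0.0), (100.0, 0.0)])
        with pytest.raises(ValueError, match="undefined"):
            fv_curve(ms, "ss")


class TestGvCurve:
    def _family(self, scale=1.0, gmax=1.0, leak_b=0.01, noise=0.0, rng=None):
        # tail currents after repolarisation proportional to a Boltzmann
        # G(V): V_half = 20 mV, slope 10 mV; ohmic leak everywhere
        dt = 0.5
        hold = -60.0
        t = np.arange(1200) * dt
        traces = []
        potentials = [-100.0, -80.0, -40.0, 0.0, 20.0, 40.0, 80.0]
        for v in potentials:
            V = np.where((t >= 100.0) & (t < 400.0), v, hold)
            g = gmax / (1.0 + np.exp(-(v - 20.0) / 10.0))
            I = leak_b * V.astype(float)
            I = I + np.where(t >= 400.0, g * (hold - (-100.0)) / 100.0, 0.0)
            I = I + np.where((t >= 100.0) & (t < 400.0), g * (v - (-100.0)) / 100.0, 0.0)
            if rng is not None and noise > 0:
                I = I + rng.normal(0, noise, len(t))
            traces.append(make_trace(np.full(len(t), 100.0), dt=dt, V=V, I=scale * I))
        return traces, potentials

    def test_boltzmann_round_trip_within_one_percent(self):
        traces, potentials = self._family()
        curve = gv_curve(traces, (100.0, 400.0), leak_potentials=[-100.0, -80.0])
        expected = 1.0 / (1.0 + np.exp(-(np.array(potentials) - 20.0) / 10.0))
        expected = expected / expected.max()
        assert np.max(np.abs(curve.y - expected)) < 0.01

    def test_scale_invariance(self):
        t1, _ = self._family(scale=1.0)
        t2, _ = self._family(scale=2.0)
        c1 = gv_curve(t1, (100.0, 400.0), leak_potentials=[-100.0, -80.0])
        c2 = gv_curve(t2, (100.0, 400.0), leak_potentials=[-100.0, -80.0])
        assert np.allclose(c1.y, c2.y, atol=1e-12)

    def test_leak_only_family_rejected(self):
        traces, _ = self._family(gmax=0.0)
        with pytest.raises(ValueError, match="undefined"):
            gv_curve(traces, (100.0, 400.0), leak_potentials=[-100.0, -80.0])

    def test_missing_current_channel_rejected(self):
        tr = make_trace(np.full(1200, 100.0))
        with pytest.raises(ValueError, match="current"):
            gv_curve([tr, tr], (100.0, 400.0), leak_potentials=[-100.0])


class TestFastComponent:
    def test_noiseless_exponential_recovered(self):
        t = np.arange(200) * 0.5
        F = 100.0 - 2.0 * (1.0 - np.exp(-t / 1.0))
        fit = fit_fast_component(make_trace(F), (0.0, 50.0))
        assert fit.identifiable
        assert fit.tau_ms == pytest.approx(1.0, abs=0.01)

    def test_clamp_speed_vs_signal_kinetics_distinguishable(self, rng):
        # the electrochromic-exclusion logic: a sub-millisecond clamp
        # artifact and a millisecond conformational signal yield
        # non-overlapping confidence intervals at recording-level noise
        t = np.arange(100) * 0.5
        taus = {0.33: [], 1.0: []}
        for tau in taus:
            for _ in range(20):
                F = 100.0 - 2.0 * (1.0 - np.exp(-t / tau)) + rng.normal(0, 0.1, len(t))
                taus[tau].append(fit_fast_component(make_trace(F), (0.0, 25.0)).tau_ms)
        lo_hi = {}
        for tau, est in taus.items():
            est = np.array(est)
            half = 1.96 * est.std(ddof=1)
            lo_hi[tau] = (est.mean() - half, est.mean() + half)
        assert lo_hi[0.33][1] < lo_hi[1.0][0]

    def test_constant_trace_flagged_unidentifiable(self):
        fit = fit_fast_component(make_trace(np.full(100, 5.0)), (0.0, 30.0))
        assert not fit.identifiable
        assert fit.amplitude == pytest.approx(0.0)
        assert np.isnan(fit.tau_ms)


class TestAttenuation:
    def test_transparent_medium(self):
        assert attenuation_fraction(AbsorbanceReading(0.0, 0.0)) == 0.0

    def test_moderate_absorbance(self):
        val = attenuation_fraction(AbsorbanceReading(0.3, 0.3))
        assert val == pytest.approx(1.0 - 10.0 ** (-0.6), rel=1e-12)
        assert val == pytest.approx(0.7488, abs=1e-4)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            AbsorbanceReading(-0.1, 0.2)

    @given(st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    def test_sum_identity_and_bounds(self, a540, a565):
        val = attenuation_fraction(AbsorbanceReading(a540, a565))
        assert val == pytest.approx(1.0 - 10.0 ** (-(a540 + a565)), rel=1e-12)
        assert 0.0 <= val < 1.0

    @given(st.floats(0.0, 2.0), st.floats(0.0, 2.0), st.floats(0.01, 1.0))
    def test_monotone_in_each_absorbance(self, a540, a565, bump):
        base = attenuation_fraction(AbsorbanceReading(a540, a565))
        assert attenuation_fraction(AbsorbanceReading(a540 + bump, a565)) > base
        assert attenuation_fraction(AbsorbanceReading(a540, a565 + bump)) > base
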