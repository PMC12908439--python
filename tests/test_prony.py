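"""Core Prony machinery: linear prediction, rooting, coefficients, fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pronypv as pv
from pronypv.prony import _power_matrix
from conftest import conj_closed_pole_set


def sig(samples, rate=1.0):
    return pv.Signal(np.asarray(samples, float), rate)


class TestSignal:
    def test_rejects_short_nonfinite_and_bad_rate(self):
        with pytest.raises(ValueError):
            pv.Signal(np.array([1.0, 2.0, 3.0]), 1.0)
        with pytest.raises(ValueError):
            pv.Signal(np.array([1.0, np.nan, 3.0, 4.0]), 1.0)
        with pytest.raises(ValueError):
            pv.Signal(np.ones(8), 0.0)

    def test_times_and_duration(self):
        s = pv.Signal(np.ones(8), 4.0, t0=1.0)
        assert s.duration == 2.0
        np.testing.assert_allclose(s.times, 1.0 + np.arange(8) / 4.0)


class TestLinearPrediction:
    @pytest.mark.parametrize(
        "samples, n, expected",
        [
            ([1, 0.5, 0.25, 0.125], 1, [0.5]),  # geometric: y_l = 0.5 y_{l-1}
            (np.cos(2 * np.pi * np.arange(8) / 8), 2, [np.sqrt(2), -1.0]),
            ([3.0, 3.0, 3.0, 3.0], 1, [1.0]),  # constant: y_l = y_{l-1}
        ],
    )
    def test_known_recurrences(self, samples, n, expected):
        lp = pv.solve_linear_prediction(sig(samples), n)
        np.testing.assert_allclose(lp.coefficients, expected, atol=1e-12)
        assert lp.residual_norm < 1e-10

    def test_order_out_of_range(self):
        s = sig(np.arange(10.0))
        with pytest.raises(ValueError):
            pv.solve_linear_prediction(s, 0)
        with pytest.raises(ValueError):
            pv.solve_linear_prediction(s, 6)  # floor(10/2) = 5 is the cap

    def test_singular_system_warns_not_crashes(self):
        s = sig(np.zeros(12))
        with pytest.warns(RuntimeWarning, match="singular"):
            lp = pv.solve_linear_prediction(s, 3)
        assert np.all(np.isfinite(lp.coefficients))


class TestPolesFromLp:
    def test_single_real_pole(self):
        lp = pv.LinearPrediction(np.array([0.5]), 1)
        np.testing.assert_allclose(pv.poles_from_lp(lp), [0.5])

    def test_conjugate_pair_from_cosine_recurrence(self):
        # x^2 - sqrt(2) x + 1 has roots e^{+-j pi/4}
        lp = pv.LinearPrediction(np.array([np.sqrt(2), -1.0]), 2)
        roots = pv.poles_from_lp(lp)
        expected = np.array([np.exp(-1j * np.pi / 4), np.exp(1j * np.pi / 4)])
        np.testing.assert_allclose(np.sort_complex(roots), np.sort_complex(expected), atol=1e-12)

    def test_unit_pole(self):
        lp = pv.LinearPrediction(np.array([1.0]), 1)
        np.testing.assert_allclose(pv.poles_from_lp(lp), [1.0])

    def test_ordering_deterministic(self):
        lp = pv.LinearPrediction(np.array([np.sqrt(2), -1.0]), 2)
        roots = pv.poles_from_lp(lp)
        # descending magnitude, ties broken by ascending phase
        assert roots[0].imag < 0 < roots[1].imag

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_independent_rootfinder(self, seed):
        """Companion-matrix roots agree with an independent polynomial
        solver for small orders (brute-force oracle)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 5))
        a = rng.normal(size=n)
        roots = pv.poles_from_lp(pv.LinearPrediction(a, n))
        # oracle: numpy's polynomial package (ascending-coefficient basis)
        coeffs = np.concatenate([-a[::-1], [1.0]])
        oracle = np.polynomial.polynomial.polyroots(coeffs)
        key = lambda z: (np.round(z.real, 9), np.round(z.imag, 9))
        for r, o in zip(sorted(roots, key=key), sorted(oracle, key=key)):
            assert abs(r - o) < 1e-9


class TestFitCoefficients:
    def test_geometric(self):
        s = sig(0.5 ** np.arange(8))
        c = pv.fit_coefficients(s, [0.5], 1.0)
        np.testing.assert_allclose(c, [1.0], atol=1e-12)

    def test_cosine_euler_split(self):
        s = sig(np.cos(2 * np.pi * np.arange(8) / 8))
        poles = np.exp(np.array([1j, -1j]) * np.pi / 4)
        c = pv.fit_coefficients(s, poles, 1.0)
        np.testing.assert_allclose(c, [0.5, 0.5], atol=1e-12)
        # brute-force least squares oracle
        vmat = np.vander(poles, 8, increasing=True).T
        oracle, *_ = np.linalg.lstsq(vmat, s.samples, rcond=None)
        np.testing.assert_allclose(c, oracle, atol=1e-12)

    def test_zero_signal_gives_zero_coefficients(self):
        s = sig(np.zeros(8))
        c = pv.fit_coefficients(s, [0.5, 0.9j], 1.0)
        np.testing.assert_allclose(c, 0, atol=1e-14)

    def test_empty_poles_rejected(self):
        with pytest.raises(ValueError):
            pv.fit_coefficients(sig(np.ones(4)), [], 1.0)


class TestComponentsFromPoles:
    @pytest.mark.parametrize(
        "mu, c, expected",
        [
            (np.exp(1j * np.pi / 2), 0.5, (0.5, 0.0, 0.25, 0.0)),
            (0.5, 1.0, (1.0, math.log(0.5), 0.0, 0.0)),
            (1.0, 1 + 1j, (math.sqrt(2), 0.0, 0.0, math.pi / 4)),
        ],
    )
    def test_known_conversions(self, mu, c, expected):
        (comp,) = pv.components_from_poles([mu], [c])
        a, s, f, p = expected
        assert comp.amplitude == pytest.approx(a)
        assert comp.damping == pytest.approx(s, abs=1e-15)
        assert comp.frequency == pytest.approx(f, abs=1e-15)
        assert comp.phase == pytest.approx(p, abs=1e-15)

    def test_zero_pole_flagged(self):
        with pytest.warns(RuntimeWarning, match="origin"):
            (comp,) = pv.components_from_poles([0.0], [1.0])
        assert comp.damping == -np.inf

    @settings(derandomize=True, max_examples=40)
    @given(
        amp=st.floats(1e-3, 1e3),
        sigma=st.floats(-2.0, 1.0),
        freq=st.floats(-0.499, 0.499),
        phase=st.floats(-3.1415, 3.1415),
    )
    def test_roundtrip_parameterization(self, amp, sigma, freq, phase):
        """mu = e^{sigma+2j pi f}, C = A e^{j phi} invert exactly."""
        mu = np.exp(sigma + 2j * np.pi * freq)
        c = amp * np.exp(1j * phase)
        (comp,) = pv.components_from_poles([mu], [c])
        assert comp.damping == pytest.approx(sigma, rel=1e-9, abs=1e-12)
        assert comp.frequency == pytest.approx(freq, rel=1e-9, abs=1e-12)
        assert comp.amplitude == pytest.approx(amp, rel=1e-12)
        assert comp.phase == pytest.approx(phase, rel=1e-9, abs=1e-12)


class TestEvaluateModel:
    def _model(self, poles, coeffs, m=8, d=1.0, rate=1.0):
        return pv.PronyModel(
            poles=np.asarray(poles, complex),
            coefficients=np.asarray(coeffs, complex),
            n_components=len(poles),
            scale_d=d,
            sampling_rate=rate,
            source_length=m,
        )

    def test_conjugate_pair_gives_cosine(self):
        model = self._model(np.exp(np.array([1j, -1j]) * np.pi / 4), [0.5, 0.5])
        out = pv.evaluate_model(model, np.arange(8))
        np.testing.assert_allclose(out, np.cos(2 * np.pi * np.arange(8) / 8), atol=1e-12)
        assert model.imag_residual < 1e-14

    def test_empty_model_is_zero(self):
        model = self._model([], [])
        np.testing.assert_array_equal(pv.evaluate_model(model, np.arange(5)), 0.0)

    def test_unit_pole_constant(self):
        model = self._model([1.0], [2.5])
        np.testing.assert_allclose(pv.evaluate_model(model, np.arange(6)), 2.5)


class TestRSquared:
    def test_perfect_and_mean_fits(self):
        y = np.array([1.0, 2.0, 4.0, 3.0])
        assert pv.r_squared(y, y) == 1.0
        assert pv.r_squared(y, np.full(4, y.mean())) == 0.0

    def test_worse_than_mean_is_negative(self):
        assert pv.r_squared([0.0, 1.0], [1.0, 0.0]) == pytest.approx(-3.0)

    def test_constant_observed_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            pv.r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestOptimizeScale:
    def test_never_worse_than_unit_scale(self):
        s, _ = pv.make_damped_sinusoids(
            [pv.PronyComponent(1.0, -1.0, 5.0, 0.3)], 250.0, 1.0
        )
        d = pv.optimize_scale(s, 2)
        r2_d = pv.prony_fit(s, 2, d).r_squared
        r2_1 = pv.prony_fit(s, 2, 1.0).r_squared
        assert r2_d >= r2_1 - 1e-12

    def test_five_component_signal_high_r2(self):
        comps = [
            pv.PronyComponent(2.0, -1.5, 5.0, 0.4),
            pv.PronyComponent(1.0, -3.0, 11.0, -1.0),
            pv.PronyComponent(1.5, -2.0, 17.0, 1.2),
            pv.PronyComponent(0.5, -0.5, 23.0, 2.0),
            pv.PronyComponent(0.8, -4.0, 31.0, -2.2),
        ]
        s, _ = pv.make_damped_sinusoids(comps, 1000.0, 1.0)
        d = pv.optimize_scale(s, 10)
        assert pv.prony_fit(s, 10, d).r_squared > 0.99

    def test_invariant_to_linear_scaling(self):
        s, _ = pv.make_damped_sinusoids(
            [pv.PronyComponent(1.0, -1.0, 5.0, 0.3)], 250.0, 1.0
        )
        doubled = pv.Signal(2 * s.samples, s.sampling_rate)
        assert pv.optimize_scale(s, 2) == pv.optimize_scale(doubled, 2)


class TestPronyFit:
    def test_three_component_recovery(self):
        comps = [
            pv.PronyComponent(2.0, -1.5, 5.0, 0.4),
            pv.PronyComponent(1.0, -3.0, 11.0, -1.0),
            pv.PronyComponent(0.5, -0.5, 23.0, 2.0),
        ]
        s, truth = pv.make_damped_sinusoids(comps, 250.0, 1.0)
        model = pv.prony_fit(s, 6, 1.0)
        assert model.r_squared >= 1 - 1e-10
        rec = sorted(pv.physical_components(model), key=lambda c: c.frequency)
        for got, want in zip(rec, sorted(truth, key=lambda c: c.frequency)):
            assert got.amplitude == pytest.approx(want.amplitude, rel=1e-6)
            assert got.damping == pytest.approx(want.damping, rel=1e-6)
            assert got.frequency == pytest.approx(want.frequency, rel=1e-6)
            assert got.phase == pytest.approx(want.phase, rel=1e-6)

    def test_pure_cosine_poles_on_unit_circle(self):
        t = np.arange(200) / 200.0
        s = pv.Signal(np.cos(2 * np.pi * 13 * t), 200.0)
        model = pv.prony_fit(s, 2, 1.0)
        np.testing.assert_allclose(np.abs(model.poles), 1.0, atol=1e-8)

    def test_auto_order_pressure_waveform(self, pressure_1khz):
        model = pv.prony_fit(pressure_1khz)
        assert model.r_squared > 0.99
        assert model.n_components <= len(pressure_1khz) // 2

    def test_nyquist_cap_enforced(self):
        s = pv.Signal(np.sin(np.arange(10.0)), 10.0)
        with pytest.raises(ValueError):
            pv.prony_fit(s, 6, 1.0)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_round_trip_pole_recovery(self, seed):
        """evaluate_model -> prony_fit recovers a conjugate-closed pole set."""
        rng = np.random.default_rng(seed)
        poles = conj_closed_pole_set(rng, n_pairs=3, radius_hi=1.01)
        upper = rng.uniform(0.5, 2, 3) * np.exp(1j * rng.uniform(-np.pi, np.pi, 3))
        coeffs = np.concatenate([upper, np.conj(upper)])
        model = pv.PronyModel(
            poles=poles,
            coefficients=coeffs,
            n_components=6,
            scale_d=1.0,
            sampling_rate=100.0,
            source_length=100,
        )
        y = pv.evaluate_model(model, np.arange(100))
        refit = pv.prony_fit(pv.Signal(y, 100.0), 6, 1.0)
        got = np.sort_complex(refit.poles)
        want = np.sort_complex(poles)
        np.testing.assert_allclose(got, want, atol=1e-6)

    @pytest.mark.parametrize("seed", [21, 22])
    def test_conjugate_symmetry_for_real_signals(self, seed):
        rng = np.random.default_rng(seed)
        s = pv.Signal(rng.normal(size=40), 40.0)
        model = pv.prony_fit(s, 5, 1.0)
        got = np.sort_complex(model.poles)
        conj = np.sort_complex(np.conj(model.poles))
        np.testing.assert_allclose(got, conj, atol=1e-8)

    def test_imaginary_residue_negligible_for_real_fits(self, pv250):
        model = pv250["model_p"]
        pv.evaluate_model(model, np.arange(model.source_length))
        scale = np.max(np.abs(pv250["pressure"].samples))
        assert model.imag_residual <= 1e-8 * scale


def test_power_matrix_handles_zero_pole():
    v = _power_matrix(np.array([0.0 + 0j, 0.5 + 0j]), np.arange(4.0))
    np.testing.assert_allclose(v[:, 0], [1, 0, 0, 0])
    np.testing.assert_allclose(v[:, 1], 0.5 ** np.arange(4))
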