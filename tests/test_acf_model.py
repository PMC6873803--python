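"""ACF model function, effective observation area, and parameter recovery."""

import numpy as np
import pytest
from scipy import integrate

import rafttrace as rt
from rafttrace.acf import ACFModel, acf_model, acf_model_multi, amplitude_weights
from rafttrace.correlate import ACFCurve


def make_curve(lags, G):
    return ACFCurve(lags=lags, G=G, var_G=None, n_frames=len(lags) * 100,
                    trace_mean=100.0, frame_time=lags[0])


def quadrature_a_eff(a, omega0):
    """Independent oracle: A_eff = (∫∫W)²/∫∫W² with W = square ⊗ Gaussian,
    evaluated by numerical convolution quadrature (separable axes)."""

    def w(x):
        val, _ = integrate.quad(
            lambda u: np.sqrt(2.0 / np.pi) / omega0
            * np.exp(-2.0 * (x - u) ** 2 / omega0**2),
            -a / 2.0, a / 2.0, epsabs=1e-13, limit=200)
        return val

    half_width = a / 2.0 + 5.0 * omega0
    i2, _ = integrate.quad(lambda x: w(x) ** 2, -half_width, half_width,
                           epsabs=1e-13, limit=400)
    return (a * a / i2) ** 2


class TestEffectiveArea:
    def test_closed_form_matches_convolution_quadrature(self):
        omega0 = 0.24
        for ratio in (0.05, 0.5, 1.0, 2.0, 10.0):
            a = ratio * omega0
            closed = rt.effective_area(a, omega0)
            oracle = quadrature_a_eff(a, omega0)
            assert abs(closed - oracle) / oracle < 1e-3

    def test_large_pixel_limit_is_geometric_area(self):
        # A_eff/a² − 1 ≈ 2/(√π·p₀) vanishes as the PSF shrinks
        a = 1.0
        assert abs(rt.effective_area(a, a / 1e7) - a * a) < 1e-6

    def test_small_pixel_limit_is_psf_area(self):
        omega0 = 0.24
        a = 0.05 * omega0
        assert abs(rt.effective_area(a, omega0) - np.pi * omega0**2) \
            / (np.pi * omega0**2) < 0.01

    def test_monotone_in_pixel_size_and_psf_radius(self):
        grid = np.linspace(0.05, 2.0, 40)
        a_eff_a = [rt.effective_area(a, 0.24) for a in grid]
        a_eff_w = [rt.effective_area(0.5, w) for w in grid]
        assert np.all(np.diff(a_eff_a) > 0)
        assert np.all(np.diff(a_eff_w) > 0)

    def test_always_at_least_pixel_area(self):
        for a in (0.1, 0.24, 1.2):
            assert rt.effective_area(a, 0.24) >= a * a


class TestModelFunction:
    tau = np.geomspace(1e-3, 30.0, 200)

    def test_amplitude_at_zero_lag(self):
        # G(0⁺) = (1/N)(1 + F_t/(1−F_t)) + G_∞
        for n, ft, ginf in [(10.0, 0.0, 0.0), (3.0, 0.2, 0.05)]:
            g0 = acf_model(np.array([1e-12]), N=n, D=0.5, a=0.24, omega0=0.24,
                           F_t=ft, t_f=1e-3, G_inf=ginf)[0]
            expected = (1 + ft / (1 - ft)) / n + ginf
            assert abs(g0 - expected) < 1e-9

    def test_strictly_decreasing_without_triplet(self):
        g = acf_model(self.tau, N=5.0, D=1.0, a=0.24, omega0=0.24)
        assert np.all(np.diff(g) < 0)

    def test_converges_to_offset_at_long_lags(self):
        g = acf_model(np.array([1e5]), N=5.0, D=1.0, a=0.24, omega0=0.24,
                      G_inf=0.07)
        assert abs(g[0] - 0.07) < 1e-4

    def test_multi_component_reduces_to_single(self):
        single = acf_model(self.tau, N=4.0, D=0.8, a=0.24, omega0=0.24,
                           G_inf=0.01)
        multi = acf_model_multi(self.tau, alphas=[0.25], Ds=[0.8], a=0.24,
                                omega0=0.24, G_inf=0.01)
        np.testing.assert_allclose(single, multi, rtol=1e-12)

    def test_amplitude_weights_consistency(self):
        b = np.array([1.0, 3.0])
        n = np.array([10.0, 2.0])
        alpha = amplitude_weights(b, n)
        # Σ-consistency: Σ α_i = Σ B_i²N_i / (Σ B_iN_i)²
        assert abs(alpha.sum()
                   - (b**2 * n).sum() / (b * n).sum() ** 2) < 1e-12
        np.testing.assert_allclose(amplitude_weights([2.0], [8.0]), [1 / 8.0])


class TestFitting:
    def noiseless_curve(self, **params):
        defaults = dict(N=10.0, D=0.5, a=0.24, omega0=0.24, G_inf=0.0)
        defaults.update(params)
        lags = np.geomspace(3e-3, 20.0, 80)
        return make_curve(lags, acf_model(lags, **defaults)), defaults

    def test_noiseless_parameters_recovered_exactly(self):
        curve, truth = self.noiseless_curve()
        fit = ACFModel(curve, a=0.24, omega0=0.24).fit()
        assert fit.converged
        for name in ("N", "D", "G_inf"):
            assert abs(fit.params[name] - truth[name]) <= \
                1e-6 * max(abs(truth[name]), 1e-3)

    def test_triplet_term_degenerate_when_data_has_none(self):
        curve, truth = self.noiseless_curve(N=5.0, D=1.2)
        plain = ACFModel(curve, a=0.24, omega0=0.24, triplet=False).fit()
        with_triplet = ACFModel(curve, a=0.24, omega0=0.24, triplet=True).fit()
        assert abs(with_triplet.params["D"] - plain.params["D"]) \
            / plain.params["D"] < 0.01

    def test_fit_invariant_under_intensity_rescaling(self):
        # G is normalized, so the fit must not depend on trace brightness;
        # rescaling enters only through identical G values
        rng = np.random.default_rng(2)
        curve, _ = self.noiseless_curve()
        noisy = make_curve(curve.lags, curve.G + rng.normal(0, 1e-4, curve.G.size))
        f1 = ACFModel(noisy, a=0.24, omega0=0.24).fit()
        f2 = ACFModel(noisy, a=0.24, omega0=0.24).fit()
        assert f1.params == f2.params

    def test_tau_d_definition(self):
        curve, truth = self.noiseless_curve(D=2.0)
        fit = ACFModel(curve, a=0.24, omega0=0.24).fit()
        assert abs(fit.tau_D - fit.A_eff / fit.params["D"]) < 1e-12

    def test_curve_shorter_than_parameter_count_rejected(self):
        lags = np.array([1e-3, 2e-3, 3e-3])
        with pytest.raises(ValueError, match="parameters"):
            ACFModel(make_curve(lags, np.ones(3)), a=0.24, omega0=0.24)

    def test_summary_mentions_key_quantities(self):
        curve, _ = self.noiseless_curve()
        text = ACFModel(curve, a=0.24, omega0=0.24).fit().summary()
        for token in ("A_eff", "tau_D", "reduced chi^2", "D"):
            assert token in text
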