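import mpmath as mp
import numpy as np
import pytest

from amorphkit.errors import DomainError, InsufficientDataError, NotFittableError
from amorphkit.kww import (
    _kww_reduced,
    fit_kww,
    kww_fwhm_decades,
    kww_loss,
    kww_peak_x,
    kww_sum_rule,
    shape_invariance_check,
)
from amorphkit.spectra_io import LossSpectrum, SpectrumSet

from conftest import hn_spectrum

mp.mp.dps = 40


def contour_oracle(x: float, beta: float) -> float:
    """Independent high-precision (tanh-sinh, 40 digits) quadrature oracle."""
    c1, c2 = mp.cos(mp.pi * beta / 2), mp.sin(mp.pi * beta / 2)
    f = lambda y: mp.e ** (-c1 * y**beta - x * y) * mp.sin(c2 * y**beta)
    return float(x * mp.quad(f, [0, 1, 10, 100, 1000, 10000, mp.inf]))


def lobe_sum_oracle(x: float, beta: float, max_lobes: int = 2000) -> float:
    """Original-domain sine transform summed lobe by lobe between sin zeros."""
    g = lambda u: beta * u ** (beta - 1) * mp.e ** (-(u**beta)) * mp.sin(x * u)
    total = mp.mpf(0)
    for k in range(max_lobes):
        term = mp.quad(g, [k * mp.pi / x, (k + 1) * mp.pi / x])
        total += term
        if abs(term) < mp.mpf(10) ** -20 and k > 4:
            break
    return float(total)


class TestKWWTransform:
    def test_debye_limit_matches_lorentzian_everywhere(self):
        x = 10.0 ** np.linspace(-6, 6, 49)
        got = kww_loss(1.0, 1.0, 1.0, x)
        np.testing.assert_allclose(got, x / (1 + x**2), rtol=1e-6)

    @pytest.mark.parametrize("beta", [0.3, 0.62, 0.95])
    def test_agrees_with_quadrature_oracle_over_six_decades(self, beta):
        for x in 10.0 ** np.linspace(-3, 3, 13):
            expected = contour_oracle(x, beta)
            assert _kww_reduced(x, beta) == pytest.approx(expected, rel=1e-6)

    def test_half_beta_at_unit_reduced_frequency(self):
        expected = contour_oracle(1.0, 0.5)
        assert kww_loss(0.5, 1.0, 1.0, np.array([1.0]))[0] == pytest.approx(
            expected, rel=1e-8
        )

    @pytest.mark.parametrize("beta,x", [(0.62, 0.5), (0.62, 5.0), (0.95, 0.5)])
    def test_original_domain_lobe_sum_confirms_value(self, beta, x):
        assert _kww_reduced(x, beta) == pytest.approx(lobe_sum_oracle(x, beta), rel=1e-9)

    @pytest.mark.parametrize("beta", [0.3, 0.62, 1.0])
    def test_sum_rule_half_pi_amplitude(self, beta):
        assert kww_sum_rule(beta) == pytest.approx(np.pi / 2, rel=1e-3)

    def test_nonnegative_and_unimodal(self):
        x = 10.0 ** np.linspace(-4, 4, 161)
        for beta in (0.3, 0.62, 0.9):
            vals = kww_loss(beta, 1.0, 1.0, x)
            assert np.all(vals > 0)
            d = np.diff(vals)
            top = np.argmax(vals)
            assert np.all(d[:top] > 0) and np.all(d[top:] < 0)

    def test_peak_scales_with_reciprocal_tau(self):
        xp = kww_peak_x(0.62)
        for tau in (1e-3, 1.0, 1e3):
            omega = np.array([xp / tau])
            grid = omega[0] * 10 ** np.linspace(-0.05, 0.05, 11)
            vals = kww_loss(0.62, tau, 1.0, grid)
            assert np.argmax(vals) == 5

    def test_width_grows_as_beta_decreases(self):
        widths = [kww_fwhm_decades(b) for b in (0.3, 0.5, 0.7, 0.9, 1.0)]
        assert np.all(np.diff(widths) < 0)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            kww_loss(1.2, 1.0, 1.0, np.array([1.0]))
        with pytest.raises(DomainError):
            kww_loss(0.5, 1.0, 1.0, np.array([-1.0]))


def kww_spectrum(beta, tau, amplitude, f_lo=-3, f_hi=4, ppd=10, T=360.0):
    freqs = np.logspace(f_lo, f_hi, ppd * (f_hi - f_lo) + 1)
    return LossSpectrum(T, freqs, kww_loss(beta, tau, amplitude, 2 * np.pi * freqs))


class TestFitKWW:
    def test_recovers_stretching_exponent_of_bosentan_like_peak(self):
        spec = kww_spectrum(0.62, 1.6e-2, 7.8)  # f_max ~ 10 Hz
        fit = fit_kww(spec)
        assert fit.beta == pytest.approx(0.62, abs=0.005)
        assert fit.tau_kww == pytest.approx(1.6e-2, rel=0.01)
        assert fit.amplitude == pytest.approx(7.8, rel=0.01)

    def test_debye_peak_gives_unit_beta(self):
        spec = kww_spectrum(1.0, 1e-2, 5.0)
        assert fit_kww(spec).beta == pytest.approx(1.0, abs=1e-3)

    def test_hn_peak_beta_matches_grid_search_oracle(self):
        spec = hn_spectrum(1.0, 1.0, 0.8, 0.6, 0.0, f_lo=-4, f_hi=4)
        fit = fit_kww(spec)
        # exhaustive grid over (beta, tau); amplitude profiled in log space
        idx = np.argmax(spec.loss)
        f_peak = spec.frequencies[idx]
        sel = np.abs(np.log10(spec.frequencies / f_peak)) <= 2.0
        omega = 2 * np.pi * spec.frequencies[sel]
        log_loss = np.log10(spec.loss[sel])
        best = (np.inf, None)
        for beta in np.linspace(0.35, 0.9, 40):
            for ltau in np.linspace(np.log10(1 / (2 * np.pi * f_peak)) - 1, np.log10(1 / (2 * np.pi * f_peak)) + 1, 25):
                model = np.log10(kww_loss(beta, 10.0**ltau, 1.0, omega))
                amp = np.mean(log_loss - model)
                rss = np.sum((model + amp - log_loss) ** 2)
                if rss < best[0]:
                    best = (rss, beta)
        assert fit.beta == pytest.approx(best[1], abs=0.03)
        # empirical interconversion sanity band beta ~ (a*b)^(1/1.23) ~ 0.55
        assert 0.45 <= fit.beta <= 0.65

    def test_no_peak_raises_not_fittable(self):
        freqs = np.logspace(0, 4, 41)
        spec = LossSpectrum(350.0, freqs, 1.0 / freqs**0.6)
        with pytest.raises(NotFittableError):
            fit_kww(spec)


class TestShapeInvariance:
    def test_fixed_shape_ladder_has_tight_spread(self, default_ladder):
        from amorphkit.hn_fit import fit_hn

        sigmas = {s.temperature: fit_hn(s).sigma_over_eps0 for s in default_ladder}
        result = shape_invariance_check(default_ladder, sigmas=sigmas)
        assert result.spread < 0.01
        assert result.passed

    def test_injected_shape_change_fails_threshold(self):
        s1 = kww_spectrum(0.5, 1e-2, 5.0, T=360.0)
        s2 = kww_spectrum(0.9, 1e-3, 5.0, T=365.0)
        result = shape_invariance_check(SpectrumSet([s1, s2]), threshold=0.05)
        assert not result.passed
        assert result.spread > 0.3

    def test_single_fittable_spectrum_is_insufficient(self):
        s1 = kww_spectrum(0.6, 1e-2, 5.0, T=360.0)
        freqs = np.logspace(0, 4, 41)
        flank = LossSpectrum(340.0, freqs, 1.0 / freqs**0.6)
        with pytest.raises(InsufficientDataError):
            shape_invariance_check(SpectrumSet([s1, flank]))
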