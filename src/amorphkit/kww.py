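"""One-sided Fourier transform of the Kohlrausch-Williams-Watts (stretched
exponential) relaxation function, and beta_KWW fitting of alpha-loss peaks.

The dielectric loss of a KWW decay phi(t) = exp(-(t/tau)^beta) is

    eps''(omega) = A * integral_0^inf (-dphi/dt) sin(omega t) dt,

a Fourier sine transform with no closed form for 0 < beta < 1 (beta = 1 is
the Debye Lorentzian).  With x = omega*tau the reduced transform L(x; beta)
is computed to <= 1e-6 relative accuracy over at least x in [1e-3, 1e3] by
piecing together three schemes:

* ``x >= 2`` - the power series in x^(-beta),
  L = sum_n (-1)^(n+1) Gamma(n beta + 1)/n! * sin(n pi beta / 2) x^(-n beta),
  convergent for every x when beta < 1 and free of cancellation once x >= 2;
* ``x < 0.3`` with beta >= 0.9 - the alternating moment expansion
  L = sum_k (-1)^k x^(2k+1) Gamma((2k+1)/beta + 1)/(2k+1)!, truncated at its
  smallest term (asymptotic for beta < 1, but far below 1e-9 relative in
  this corner, where the oscillatory integral itself is hardest);
* otherwise - adaptive quadrature after rotating the Fourier contour onto
  the imaginary axis, which trades the oscillatory sine kernel for a damped
  Laplace-type integrand:
  L = x * integral_0^inf exp(-cos(pi b/2) y^b - x y) sin(sin(pi b/2) y^b) dy.
  The rotation is legitimate because exp(-z^beta) is bounded in the first
  quadrant for beta < 1 and the arc contribution vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import gammaln

from .errors import DomainError, FitFailureError, InsufficientDataError, NotFittableError
from .spectra_io import LossSpectrum, SpectrumSet

_X_SERIES = 2.0       # large-x power series above this
_X_MOMENT = 0.3       # moment expansion below this (only for beta >= 0.9)
_BETA_MOMENT = 0.9


def _kww_series_large(x: float, beta: float, max_terms: int = 400) -> float:
    """Convergent power series in x^(-beta); reliable for x >= ~2."""
    total = 0.0
    log_x = np.log(x)
    for n in range(1, max_terms + 1):
        s = np.sin(n * np.pi * beta / 2.0)
        log_mag = gammaln(n * beta + 1.0) - gammaln(n + 1.0) - n * beta * log_x
        term = (-1.0) ** (n + 1) * s * np.exp(log_mag)
        total += term
        if np.exp(log_mag) < 1e-17 * max(abs(total), 1e-300) and n > 3:
            return total
    return total  # pragma: no cover - series always converges well before 400


def _kww_series_small(x: float, beta: float) -> float:
    """Alternating moment expansion, truncated at the smallest term."""
    total, prev_mag = 0.0, np.inf
    log_x = np.log(x)
    for k in range(0, 60):
        m = 2 * k + 1
        log_mag = m * log_x + gammaln(m / beta + 1.0) - gammaln(m + 1.0)
        mag = np.exp(log_mag)
        if mag > prev_mag:  # asymptotic series started diverging
            break
        total += (-1.0) ** k * mag
        if mag < 1e-17 * max(abs(total), 1e-300):
            break
        prev_mag = mag
    return total


def _kww_quad(x: float, beta: float) -> float:
    """Rotated-contour (Laplace-form) quadrature, non-oscillatory for beta < 1."""
    c1 = np.cos(np.pi * beta / 2.0)
    c2 = np.sin(np.pi * beta / 2.0)

    def integrand(y):
        yb = y**beta
        return np.exp(-c1 * yb - x * y) * np.sin(c2 * yb)

    val, _ = quad(integrand, 0.0, np.inf, epsabs=1e-14, epsrel=1e-11, limit=800)
    return x * val


def _kww_reduced(x: float, beta: float) -> float:
    """Reduced KWW loss L(x) = sine transform of -dphi/dt at x = omega*tau."""
    if beta == 1.0:
        return x / (1.0 + x * x)
    if x >= _X_SERIES:
        return _kww_series_large(x, beta)
    if x <= _X_MOMENT and beta >= _BETA_MOMENT:
        return _kww_series_small(x, beta)
    return _kww_quad(x, beta)


def kww_loss(beta: float, tau: float, amplitude: float, omega) -> np.ndarray:
    """Dielectric loss of a KWW relaxation on an angular-frequency grid.

    Parameters
    ----------
    beta : float
        Stretching exponent, 0 < beta <= 1 (1 = Debye).
    tau : float
        KWW relaxation time in seconds.
    amplitude : float
        Dielectric-strength scale multiplying the unit-area transform.
    omega : array_like
        Angular frequencies in rad s^-1, all positive.
    """
    if not (0.0 < beta <= 1.0):
        raise DomainError("beta must lie in (0, 1]")
    if tau <= 0:
        raise DomainError("tau must be positive")
    omega = np.asarray(omega, dtype=float)
    scalar = omega.ndim == 0
    omega = np.atleast_1d(omega)
    if np.any(omega <= 0):
        raise DomainError("omega must be positive")
    x = omega * tau
    out = np.array([_kww_reduced(xi, beta) for xi in x]) * amplitude
    return float(out[0]) if scalar else out


@lru_cache(maxsize=256)
def kww_peak_x(beta: float) -> float:
    """Reduced frequency x = omega*tau of the loss maximum for given beta."""
    if beta == 1.0:
        return 1.0
    res = minimize_scalar(
        lambda lx: -_kww_reduced(10.0**lx, beta),
        bounds=(-2.0, 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return 10.0**res.x


def kww_fwhm_decades(beta: float) -> float:
    """Full width at half maximum of the loss peak, in decades of frequency."""
    xp = kww_peak_x(beta)
    peak = _kww_reduced(xp, beta)
    half = peak / 2.0

    def _cross(lo, hi):
        from scipy.optimize import brentq

        return brentq(lambda lx: _kww_reduced(10.0**lx, beta) - half, lo, hi, xtol=1e-10)

    lxp = np.log10(xp)
    lo = _cross(lxp - 12.0, lxp)
    hi = _cross(lxp, lxp + 12.0)
    return hi - lo


def kww_sum_rule(beta: float, amplitude: float = 1.0, n: int = 4001, decades: float = 32.0) -> float:
    """Numerically integrate the loss over ln(omega); exact value (pi/2)*A."""
    lx = np.linspace(-decades / 2, decades / 2, n) * np.log(10.0)
    vals = np.array([_kww_reduced(np.exp(v), beta) for v in lx])
    return amplitude * float(np.trapezoid(vals, lx))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class KWWParams:
    """Fitted stretched-exponential peak-shape parameters."""

    beta: float
    tau_kww: float
    amplitude: float
    stderr: dict = field(default_factory=dict)
    residual_norm: float = np.nan

    def __post_init__(self):
        if not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")
        if self.tau_kww <= 0 or self.amplitude <= 0:
            raise ValueError("tau_kww and amplitude must be positive")


_BETA_STARTS = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def fit_kww(
    spectrum: LossSpectrum,
    window_decades: float = 2.0,
    sigma_over_eps0: float = 0.0,
    conductivity_mode: str = "subtract",
    n_refine: int = 2,
) -> KWWParams:
    """Fit the KWW transform to the alpha-loss peak of one spectrum.

    The conductivity contribution is removed first: ``subtract`` removes
    ``sigma_over_eps0/omega`` (typically from a prior HN fit), ``mask`` drops
    points whose local log-log slope is steeper than -0.95.  The fit then
    runs in log10(loss) space over +/- ``window_decades`` around the peak,
    multi-started on a beta grid with the two best starts refined.

    Raises
    ------
    NotFittableError
        No interior loss maximum in the window after conductivity removal.
    """
    from .hn_fit import find_loss_peak, local_log_slope

    idx, f_peak = find_loss_peak(spectrum)  # raises NotFittableError on flanks
    freqs = spectrum.frequencies
    omega = 2 * np.pi * freqs
    raw = spectrum.loss
    sel = np.abs(np.log10(freqs / f_peak)) <= window_decades
    if conductivity_mode == "subtract":
        corrected = raw - sigma_over_eps0 / omega
        # a point whose signal is mostly conductivity carries amplified noise
        # after subtraction; drop it rather than let it steer the shape fit
        keep = sel & (corrected > 0.25 * raw)
    elif conductivity_mode == "mask":
        corrected = raw.copy()
        keep = sel & (local_log_slope(spectrum) > -0.95)
    else:
        raise ValueError("conductivity_mode must be 'subtract' or 'mask'")
    if keep.sum() < 5:
        raise NotFittableError("too few usable points after conductivity removal")
    omega_w, loss_w = omega[keep], corrected[keep]
    loss_peak = float(spectrum.loss[idx])
    log_loss = np.log10(loss_w)

    def resid(x):
        lbeta, ltau, lamp = x
        model = kww_loss(float(np.clip(lbeta, 1e-3, 1.0)), 10.0**ltau, 10.0**lamp, omega_w)
        return np.log10(np.maximum(model, 1e-300)) - log_loss

    # coarse stage: score each candidate beta with peak-anchored tau and amplitude
    starts = []
    for b0 in _BETA_STARTS:
        xp = kww_peak_x(b0)
        tau0 = xp / (2 * np.pi * f_peak)
        amp0 = loss_peak / _kww_reduced(xp, b0)
        x0 = np.array([b0, np.log10(tau0), np.log10(amp0)])
        starts.append((float(np.sum(resid(x0) ** 2)), x0))
    starts.sort(key=lambda t: t[0])

    best = None
    for _, x0 in starts[:n_refine]:
        try:
            res = least_squares(
                resid,
                x0,
                bounds=([1e-3, -15.0, -6.0], [1.0, 15.0, 6.0]),
                xtol=1e-13,
                ftol=1e-13,
                gtol=1e-13,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError("no KWW fit start converged")

    beta, ltau, lamp = best.x
    dof = max(best.fun.size - 3, 1)
    s2 = 2 * best.cost / dof
    try:
        se = np.sqrt(np.clip(np.diag(s2 * np.linalg.pinv(best.jac.T @ best.jac)), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(3, np.nan)
    ln10 = np.log(10.0)
    return KWWParams(
        beta=float(beta),
        tau_kww=10.0**ltau,
        amplitude=10.0**lamp,
        stderr={
            "beta": float(se[0]),
            "tau_kww": 10.0**ltau * ln10 * float(se[1]),
            "amplitude": 10.0**lamp * ln10 * float(se[2]),
        },
        residual_norm=float(np.linalg.norm(best.fun)),
    )


@dataclass
class ShapeInvarianceResult:
    """Per-temperature beta_KWW values and their spread."""

    temperatures: np.ndarray
    betas: np.ndarray
    spread: float
    threshold: float
    passed: bool


def shape_invariance_check(
    spectra: SpectrumSet,
    threshold: float = 0.05,
    sigmas: dict | None = None,
    full_window_only: bool = True,
    window_decades: float = 2.0,
    **fit_kwargs,
) -> ShapeInvarianceResult:
    """Fit beta_KWW at every peak-bearing temperature and test its spread.

    ``sigmas`` optionally maps temperature -> sigma_over_eps0 (from prior HN
    fits) for conductivity subtraction.  With ``full_window_only`` (default)
    only spectra whose peak sits at least ``window_decades`` from both grid
    edges enter the comparison: a truncated fit window biases beta and would
    masquerade as a shape change.  The filter is relaxed automatically if it
    would leave fewer than two spectra.  Requires >= 2 fittable spectra.
    """
    from .hn_fit import find_loss_peak

    def _fittable(subset):
        temps, betas = [], []
        for s in subset:
            sigma = (sigmas or {}).get(s.temperature, 0.0)
            try:
                params = fit_kww(
                    s, window_decades=window_decades, sigma_over_eps0=sigma, **fit_kwargs
                )
            except (NotFittableError, FitFailureError):
                continue
            temps.append(s.temperature)
            betas.append(params.beta)
        return temps, betas

    pool = list(spectra)
    if full_window_only:
        centered = []
        for s in pool:
            try:
                _, f_peak = find_loss_peak(s)
            except NotFittableError:
                continue
            margin_lo = np.log10(f_peak / s.frequencies[0])
            margin_hi = np.log10(s.frequencies[-1] / f_peak)
            if min(margin_lo, margin_hi) >= window_decades:
                centered.append(s)
        if len(centered) >= 2:
            pool = centered
    temps, betas = _fittable(pool)
    if len(betas) < 2:
        raise InsufficientDataError("shape invariance needs >= 2 fittable spectra")
    betas = np.array(betas)
    spread = float(betas.max() - betas.min())
    return ShapeInvarianceResult(
        temperatures=np.array(temps),
        betas=betas,
        spread=spread,
        threshold=threshold,
        passed=spread <= threshold,
    )
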