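"""Conversion of HN times to structural relaxation times, VFT fitting, and
extraction of the glass-transition temperature at tau_alpha = 100 s.

tau_alpha is defined from the loss-peak maximum,

    tau_alpha = tau_HN * [sin(pi a/(2+2b))]^(-1/a) * [sin(pi a b/(2+2b))]^(1/a),

which makes tau_alpha the reciprocal angular peak frequency of the fitted
HN function.  Relaxation times in the supercooled liquid follow the
Vogel-Fulcher-Tammann law tau(T) = tau_inf * exp(B / (T - T0)); the
dielectric Tg convention used throughout is Tg = T(tau_alpha = 100 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitFailureError, InsufficientDataError
from .hn_fit import HNParams
from .spectra_io import RelaxationMap, RelaxationSource

#: Conventional reference relaxation time defining the dielectric Tg, seconds.
TAU_REF_TG = 100.0


@dataclass
class VFTParams:
    """VFT parameters tau(T) = tau_inf * exp(B / (T - T0)).

    ``covariance`` is the 3x3 covariance of (log10 tau_inf, B, T0) from the
    fit, used for first-order propagation into Tg.
    """

    tau_inf: float
    B: float
    T0: float
    covariance: np.ndarray | None = None
    residual_norm: float = np.nan

    def __post_init__(self):
        if self.tau_inf <= 0:
            raise ValueError("tau_inf must be positive")
        if self.B <= 0:
            raise ValueError("B must be positive")
        if self.T0 < 0:
            raise ValueError("T0 must be >= 0")

    def tau(self, temperature) -> np.ndarray | float:
        """Relaxation time (s) at the given temperature(s) in K."""
        T = np.asarray(temperature, dtype=float)
        if np.any(T <= self.T0):
            raise DomainError("temperature must exceed T0")
        out = self.tau_inf * np.exp(self.B / (T - self.T0))
        return float(out) if np.isscalar(temperature) else out

    def log10_tau(self, temperature):
        T = np.asarray(temperature, dtype=float)
        if np.any(T <= self.T0):
            raise DomainError("temperature must exceed T0")
        out = np.log10(self.tau_inf) + self.B / (T - self.T0) / np.log(10.0)
        return float(out) if np.isscalar(temperature) else out

    def fragility(self, tau_ref: float = TAU_REF_TG) -> float:
        """Steepness index m = B*Tg / (ln10 * (Tg - T0)^2) at Tg(tau_ref)."""
        tg = tg_from_vft(self, tau_ref).tg
        return self.B * tg / (np.log(10.0) * (tg - self.T0) ** 2)


@dataclass
class TgEstimate:
    """Glass-transition temperature at tau_alpha = tau_ref with uncertainty."""

    tg: float
    tau_ref: float = TAU_REF_TG
    uncertainty: float = 0.0


def tau_alpha_from_hn(params: HNParams) -> float:
    """Structural relaxation time (s) from HN parameters.

    Equals 1 / (2 pi f_max) for the same parameters by construction.
    """
    a, b = params.a, params.b
    s1 = np.sin(np.pi * a / (2 + 2 * b))
    s2 = np.sin(np.pi * a * b / (2 + 2 * b))
    return params.tau_hn * s1 ** (-1.0 / a) * s2 ** (1.0 / a)


def tau_hn_from_alpha(tau_alpha: float, a: float, b: float) -> float:
    """Invert :func:`tau_alpha_from_hn` at fixed shape exponents."""
    s1 = np.sin(np.pi * a / (2 + 2 * b))
    s2 = np.sin(np.pi * a * b / (2 + 2 * b))
    return tau_alpha * s1 ** (1.0 / a) * s2 ** (-1.0 / a)


def fit_vft(points: RelaxationMap, n_t0_starts: int = 11) -> VFTParams:
    """Least-squares VFT fit of log10 tau_alpha vs temperature.

    Only points with source ``hn_fit`` enter the fit (master-shift points are
    predictions, not measurements).  Requires >= 4 points spanning >= 2
    decades of tau_alpha.  Multi-start over a T0 grid from 0 K to
    (min T - 5 K); ties break by residual then smaller T0.
    """
    measured = points.subset(RelaxationSource.HN_FIT)
    T = measured.temperatures
    y = measured.log10_tau
    if T.size < 4:
        raise InsufficientDataError("VFT fit needs >= 4 measured points")
    if y.max() - y.min() < 2.0:
        raise InsufficientDataError("VFT fit needs >= 2 decades of tau_alpha")

    def resid(x):
        lt_inf, B, T0 = x
        return lt_inf + B / (T - T0) / np.log(10.0) - y

    t0_grid = np.linspace(0.0, T.min() - 5.0, n_t0_starts)
    best = None
    for t0 in t0_grid:
        # linearize: y = lt_inf + (B/ln10) * 1/(T - t0)
        A = np.column_stack([np.ones_like(T), 1.0 / (T - t0)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        x0 = np.array([coef[0], max(coef[1] * np.log(10.0), 1.0), t0])
        try:
            res = least_squares(
                resid,
                x0,
                bounds=([-30.0, 1e-6, 0.0], [10.0, 1e5, T.min() - 1e-6]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:
            continue
        if not res.success:
            continue
        if (
            best is None
            or res.cost < best.cost * (1 - 1e-12)
            or (abs(res.cost - best.cost) <= 1e-12 * max(best.cost, 1e-300) and res.x[2] < best.x[2])
        ):
            best = res
    if best is None:
        raise FitFailureError("no VFT start converged")

    lt_inf, B, T0 = best.x
    dof = max(T.size - 3, 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = None
    return VFTParams(
        tau_inf=10.0 ** lt_inf,
        B=float(B),
        T0=float(T0),
        covariance=cov,
        residual_norm=float(np.linalg.norm(best.fun)),
    )


def tg_from_vft(params: VFTParams, tau_ref: float = TAU_REF_TG) -> TgEstimate:
    """Closed-form Tg = T0 + B / ln(tau_ref / tau_inf), with propagated error.

    Raises :class:`DomainError` when tau_ref <= tau_inf (the VFT curve never
    reaches tau_ref above T0).
    """
    if tau_ref <= params.tau_inf:
        raise DomainError("tau_ref must exceed tau_inf")
    ln_ratio = np.log(tau_ref / params.tau_inf)
    tg = params.T0 + params.B / ln_ratio
    unc = 0.0
    if params.covariance is not None:
        # gradient wrt (log10 tau_inf, B, T0)
        g = np.array([params.B * np.log(10.0) / ln_ratio**2, 1.0 / ln_ratio, 1.0])
        var = float(g @ params.covariance @ g)
        unc = float(np.sqrt(max(var, 0.0)))
    return TgEstimate(tg=float(tg), tau_ref=tau_ref, uncertainty=unc)
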