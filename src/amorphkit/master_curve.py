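"""Master-curve (time-temperature superposition) prediction of glassy-state
relaxation times.

Below Tg the alpha peak sits outside the measurable frequency window and
only its high-frequency flank is visible.  When the peak shape is
temperature invariant, a sub-Tg flank superposes onto a supercooled-liquid
reference spectrum after a horizontal shift ``s`` along log10 frequency,
and the shift converts directly into a relaxation time:

    log10 tau_alpha(T) = log10 tau_alpha(T_ref) - s(T).

Sign convention: ``s`` is the signed displacement of the *reference* curve
along log10 f (rightward positive) that lands it on the target, i.e.
``s = log10(tau_alpha(T_ref) / tau_alpha(T_target))``; shifting the
reference toward lower frequencies (s < 0) therefore predicts a slower
target.  Shifts are horizontal only; any remaining vertical offset is
reported as a diagnostic, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InsufficientOverlapError
from .spectra_io import LossSpectrum, RelaxationMap, RelaxationPoint, RelaxationSource
from .vft_analysis import VFTParams


@dataclass
class ShiftResult:
    """Horizontal shift of the reference spectrum onto one target spectrum."""

    temperature: float
    log10_shift: float
    overlap_points: int
    objective_value: float
    predicted_log10_tau: float = np.nan
    shift_uncertainty: float = np.nan
    vertical_residual: float = np.nan


def _prepare(spectrum: LossSpectrum, sigma_over_eps0: float, noise_floor: float):
    """Log-log points with the conductivity contribution removed/excluded.

    Points are dropped when (a) the conductivity-corrected loss is not
    positive, (b) it falls below the noise floor, or (c) the local log-log
    slope is steeper than -0.95 (conductivity-dominated tail).
    """
    x = np.log10(spectrum.frequencies)
    loss = spectrum.loss - sigma_over_eps0 / (2 * np.pi * spectrum.frequencies)
    keep = loss > max(noise_floor, 0.0)
    y = np.log10(np.maximum(loss, 1e-300))
    if keep.sum() >= 3:
        slope = np.gradient(y, x)
        keep &= slope > -0.95
    return x[keep], y[keep]


def estimate_shift(
    reference: LossSpectrum,
    target: LossSpectrum,
    sigma_reference: float = 0.0,
    sigma_target: float = 0.0,
    noise_floor: float = 0.0,
    min_overlap: int = 5,
    scan_halfwidth: float = 8.0,
    scan_step: float = 0.1,
) -> ShiftResult:
    """Find the horizontal log10-frequency shift superposing reference on target.

    A coarse pre-scan on a ``scan_step``-decade grid over +/-
    ``scan_halfwidth`` decades avoids local minima; the best bracket is then
    polished with bounded scalar minimization.  The objective is the mean
    squared difference of log10 loss over the overlap region, with the
    reference interpolated linearly in log-log space.

    Raises
    ------
    InsufficientOverlapError
        Fewer than ``min_overlap`` target points remain in the overlap at
        every candidate shift.
    """
    xr, yr = _prepare(reference, sigma_reference, noise_floor)
    xt, yt = _prepare(target, sigma_target, noise_floor)
    if xr.size < 2 or xt.size < min_overlap:
        raise InsufficientOverlapError("not enough usable points after masking")

    def objective(s: float) -> tuple[float, int]:
        lo, hi = xr[0] + s, xr[-1] + s
        sel = (xt >= lo) & (xt <= hi)
        n = int(sel.sum())
        if n < min_overlap:
            return np.inf, n
        interp = np.interp(xt[sel] - s, xr, yr)
        return float(np.mean((interp - yt[sel]) ** 2)), n

    grid = np.arange(-scan_halfwidth, scan_halfwidth + scan_step / 2, scan_step)
    vals = np.array([objective(s)[0] for s in grid])
    if not np.any(np.isfinite(vals)):
        raise InsufficientOverlapError(
            f"overlap below {min_overlap} points at every shift in +/-{scan_halfwidth} decades"
        )
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda s: objective(s)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    s_best = float(res.x)
    obj, n_overlap = objective(s_best)

    # curvature-based uncertainty and residual vertical offset diagnostics
    h = 1e-3
    f0, fp = obj, objective(s_best + h)[0]
    fm = objective(s_best - h)[0]
    curv = (fp + fm - 2 * f0) / h**2
    unc = float(np.sqrt(2 * f0 / (n_overlap * curv))) if curv > 0 and np.isfinite(fp + fm) else np.nan
    sel = (xt >= xr[0] + s_best) & (xt <= xr[-1] + s_best)
    vert = float(np.mean(np.interp(xt[sel] - s_best, xr, yr) - yt[sel]))

    return ShiftResult(
        temperature=target.temperature,
        log10_shift=s_best,
        overlap_points=n_overlap,
        objective_value=obj,
        shift_uncertainty=unc,
        vertical_residual=vert,
    )


def predict_glassy_tau(
    reference_tau_alpha: float, shifts: list[ShiftResult]
) -> RelaxationMap:
    """Convert shift results into predicted relaxation-map points.

    log10 tau_alpha(T) = log10 tau_alpha(T_ref) - s(T).
    """
    log_ref = np.log10(reference_tau_alpha)
    points = []
    for sh in shifts:
        pred = log_ref - sh.log10_shift
        sh.predicted_log10_tau = pred
        unc = sh.shift_uncertainty if np.isfinite(sh.shift_uncertainty) else 0.0
        points.append(
            RelaxationPoint(sh.temperature, pred, RelaxationSource.MASTER_SHIFT, unc)
        )
    return RelaxationMap(points)


@dataclass
class VFTDeviation:
    """Signed log10 deviations of predicted points from a VFT extrapolation.

    Positive deviation = slower than the VFT extrapolation, the signature of
    a more aged glass.
    """

    temperatures: np.ndarray
    deviations: np.ndarray
    mean: float
    max_abs: float


def compare_to_vft(predicted: RelaxationMap, vft: VFTParams) -> VFTDeviation:
    """Per-point signed deviation (decades) of predictions from the VFT curve."""
    T = predicted.temperatures
    dev = predicted.log10_tau - vft.log10_tau(T)
    return VFTDeviation(
        temperatures=T,
        deviations=dev,
        mean=float(np.mean(dev)),
        max_abs=float(np.max(np.abs(dev))),
    )
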