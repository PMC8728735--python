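# Methods

This note documents the models, numerical schemes and design choices behind
`amorphkit`, and what the synthetic-data tests do and do not demonstrate
about real measurements.

## Dielectric loss model

Each spectrum is one temperature's dielectric loss ε″ versus frequency. The
fitted model is the Havriliak–Negami (HN) function with a dc-conductivity
term,

    ε″(ω) = σ_DC/(ε₀ ω) − Im[ Δε / (1 + (i ω τ_HN)^a)^b ],

with dielectric strength Δε > 0, relaxation time τ_HN > 0, symmetric
broadening exponent a and asymmetric exponent b (0 < a, b ≤ 1; a = b = 1 is
the Debye limit). The conductivity is carried as the single rate
σ_DC/ε₀ (s⁻¹), and its frequency exponent is fixed at 1 (pure dc
transport). Only ε″ is fitted; the real permittivity is an optional
pass-through column that never enters the objective, so ε_∞ plays no role.

**Fitting.** Residuals are taken in log₁₀(ε″): the spectrum spans several
decades and linear residuals would let the peak crest dominate while
ignoring the conductivity tail. Multi-start least squares
(`scipy.optimize.least_squares`, trust-region reflective) runs from the
shape grid {1.0, 0.8, 0.6, 0.4} × {1.0, 0.6} with two τ initializations per
shape pair (16 starts), τ anchored at the apparent peak. Bounds are
(10⁻³, 1] on both exponents (the open lower bound implemented as a closed
one at 10⁻³); ties across starts break by residual norm, then smaller
τ_HN. Standard errors come from the Gauss–Newton covariance with
delta-method transformation for log-parameterized quantities.

**Peak detection.** The α peak is located on a sliding-window local
log-log slope: dc tails run at slope −1 and HN high-frequency flanks at
−a·b, while the peak crest is locally flat, so candidate points are those
with slope > −0.35. A spectrum with no interior crest is classified as a
flank-only (glassy) spectrum and routed to the master-curve stage. This
makes routing robust to a conductivity maximum at the window edge, which a
naive argmax misreads as a peak.

**Sum rule.** ∫ ε″_HN d(ln ω) = (π/2)·Δε is used as a numerical
self-consistency check (trapezoid over 24 decades centred on 1/τ_HN).

## α-relaxation time and peak frequency

    τ_α = τ_HN · [sin(πa/(2+2b))]^(−1/a) · [sin(πab/(2+2b))]^(1/a)

is the reciprocal angular frequency of the loss maximum; the closed-form
peak frequency f_max = (2πτ_HN)⁻¹·[sin(πa/(2+2b))/sin(πab/(2+2b))]^(1/a)
is the same statement and both are cross-checked against a 10⁶-point
numeric argmax in the tests.

## KWW transform

The α-peak shape is quantified by β_KWW, fitting

    ε″(ω) = A · ∫₀^∞ (−dφ/dt) sin(ωt) dt,   φ(t) = exp(−(t/τ)^β).

With x = ωτ, the reduced transform L(x; β) is computed by three schemes
(switch points chosen where the methods' accuracy regions overlap, each
validated against 40-digit mpmath quadrature and an original-domain
lobe-by-lobe sum):

1. **x ≥ 2** — the power series
   L = Σₙ (−1)^(n+1) Γ(nβ+1)/n! · sin(nπβ/2) · x^(−nβ),
   convergent for every x > 0 when β < 1; for x ≥ 2 the terms decay from
   n = 1 so there is no cancellation. Terms are accumulated in log-Gamma
   form until below 10⁻¹⁷ relative.
2. **x ≤ 0.3 and β ≥ 0.9** — the alternating moment expansion
   L = Σₖ (−1)^k x^(2k+1) Γ((2k+1)/β+1)/(2k+1)!, truncated at its smallest
   term. The expansion is asymptotic for β < 1 and diverges quickly for
   small β, so it is used only in this corner — which is exactly where the
   quadrature route degrades (weak damping near the Debye limit).
3. **otherwise** — contour rotation. Because exp(−z^β) is bounded in the
   first quadrant for β ≤ 1 and the arc contribution vanishes,
   ∫₀^∞ e^(−u^β) e^(ixu) du rotates onto the imaginary axis, giving

       L(x) = x ∫₀^∞ exp(−cos(πβ/2)·y^β − x y) · sin(sin(πβ/2)·y^β) dy,

   a damped, at-most-mildly-oscillatory Laplace-type integrand that
   adaptive Gauss–Kronrod quadrature handles uniformly in x. This replaces
   oscillatory-kernel integration of the original transform, whose cycle
   length 2π/x exceeds the integrand's decay length at small x and defeats
   cycle-based accelerators.

Accuracy: ≤10⁻⁶ relative over at least x ∈ [10⁻³, 10³] for all
β ∈ (0, 1] (measured ~10⁻¹⁵ against the oracles over the tested grid).

**β fitting.** The conductivity contribution from the prior HN fit is
subtracted by default (a masking-only mode drops points with local slope
steeper than −0.95 instead). Points whose corrected loss is below 25% of
the raw signal are excluded: subtracting a fitted conductivity from a
conductivity-dominated point amplifies its noise by the removed fraction,
and such points would otherwise steer the shape fit. The fit window is ±2
decades around the peak; multi-start over β ∈ {0.3, …, 1.0} with the two
best peak-anchored starts refined.

**Shape invariance.** β is fitted per temperature and the max−min spread
compared to a threshold (default 0.05). Only spectra whose peak sits at
least the window width from both grid edges enter the comparison (relaxed
automatically if fewer than two would remain): a truncated window biases β
upward by ~0.05 and would masquerade as a shape change. The master-curve
method is only valid when this check passes.

## VFT fit and T_g

log₁₀ τ_α versus T is fitted with τ(T) = τ_∞·exp(B/(T−T₀)) (natural-log
parameterization, regression on log₁₀ τ). Only measured (HN-fit) points
enter; master-shift predictions are outputs, not inputs. Multi-start over
an 11-value T₀ grid from 0 K to (min T − 5 K), each start linearized to a
least-squares seed; ≥4 points spanning ≥2 decades of τ are required. T_g
is the closed form T₀ + B/ln(τ_ref/τ_∞) at τ_ref = 100 s (the
field-standard convention), with first-order covariance propagation for
its uncertainty; note T_g decreases with increasing τ_ref. The steepness
index m = B·T_g/(ln10·(T_g−T₀)²) is reported as a derived convenience.

## Master curve

When the peak shape is temperature-invariant, a flank-only glassy spectrum
is the reference spectrum translated along log₁₀ f. The shift s is the
signed displacement of the **reference** curve (rightward positive) that
lands it on the target: s = log₁₀(τ_α(T_ref)/τ_α(T)), and the prediction
is log₁₀ τ_α(T) = log₁₀ τ_α(T_ref) − s. Shifting toward lower frequencies
(s < 0) therefore predicts a slower, more aged target. The objective is
the mean squared log-loss difference over the overlap, with the reference
interpolated linearly in log-log space; a 0.1-decade pre-scan over ±8
decades avoids local minima before bounded scalar polish. Conductivity
points are removed via the prior HN fit's σ and a local-slope ≤ −0.95
exclusion; a minimum overlap of 5 points is enforced. Shifts are
horizontal only — the remaining vertical offset is reported as a
diagnostic, never applied. Signed deviations of the predictions from the
VFT extrapolation are reported per point; positive deviation means slower
than the extrapolation, the signature of a more aged glass.

**Known limitation.** Deep below T_g the visible flank approaches a pure
power law, so the shift objective's valley flattens asymmetrically (larger
|s| compares ever-flatter curve sections). Multiplicative noise then drags
the minimizer systematically toward overestimated |s|: with the default
ladder the maximum prediction error 9 K below T_g is ~0.005 decades
noise-free, ~0.1–0.16 decades at 1% noise and ~0.2–0.3 decades at 2%
noise, always in the "slower than VFT" direction. Conclusions about aging
drawn from deep-flank predictions at a few-percent noise level should be
treated with corresponding caution.

## Synthetic data generator

The generator is the study's stand-in for unreleased raw spectra. It
emulates:

* a supercooled ladder (default 359–381 K in 2 K steps, 10⁻¹–10⁶ Hz at 10
  points/decade) whose τ_α(T) follows a generating VFT law — default
  τ_∞ = 10⁻¹⁴ s (molecular-liquid attempt time), T₀ = 300 K, and
  B = ln(100/τ_∞)·(351−300) K ≈ 1879 K so that T_g(τ_α = 100 s) is
  exactly 351 K, the dielectric T_g of amorphous bosentan;
* a temperature-invariant HN shape, default (a, b) = (0.85, 0.6437),
  calibrated once so the default shape analysis of the noiseless ladder
  returns β_KWW = 0.62 (bosentan's reported peak shape near T_g) — β from
  a windowed fit depends on the conductivity treatment, so the
  calibration targets the package's own measurement procedure rather than
  the approximate interconversion β ≈ (ab)^(1/1.23);
* Δε = 7.8, the α-relaxation dielectric strength of bosentan;
* a dc tail with σ_DC/ε₀ = c/τ_α, single coupling constant c = 1
  (σ_DC is not a reported quantity; tying it to 1/τ_α reproduces the
  −1 low-frequency slope without a second temperature law, and makes the
  generated ladder satisfy time–temperature superposition *exactly*,
  conductivity included);
* flank-only glassy spectra at requested T < T_g (peak below the window by
  construction, enforced);
* dissolution curves C(t) = C_s·(1 − exp(−kSt/V)) — the closed-form
  solution of the stationary-disc law — with defaults V = 500 mL,
  S = π·(0.4 cm)² (8 mm disc), 0–120 min sampled every 5 min, triplicate;
  C_s defaults to 0.1 mg mL⁻¹ (the saturation solubility in the test
  medium is not a published quantity; k is then set from the target
  IDR = k·C_s).

Noise is multiplicative log-normal with unit mean (loss and concentration
span decades; additive noise would be negligible at the peak and dominant
on the flanks), pointwise-independent, seed-deterministic via
`numpy.random.default_rng`.

**What passing tests do not show.** Real spectra contain secondary (β)
relaxations, electrode polarization and correlated drift, none of which
are generated; real peak shapes are only approximately
temperature-invariant; real dissolution profiles show the
solvent-mediated recrystallization kink that the generator deliberately
omits (regime detection is tested on constructed piecewise profiles
instead). Recovery results here therefore demonstrate correctness of the
estimators under their stated model, not robustness to every systematic in
laboratory data.

## Intrinsic dissolution

IDR is (V/S) times the OLS slope of concentration versus time over a
window, per replicate, with mean and sample SD across replicates — the
windowed-slope definition, not a nonlinear fit of the saturating law
(the simulator's closed form is available for the latter). Default
windows: 0–120 min (crystalline-like kinetics), 0–15 min (fast amorphous
regime), 60–120 min (post-conversion); window assignment to samples is
always user-specified. Early-window slope estimates carry a small negative
bias from saturation curvature (−0.3% at k·S·t/V = 0.006, −1.4% at 0.029);
the ≤1% estimator guarantee applies in the far-from-saturation regime
k·S·t/V < 0.02. Fold changes are ratios of IDR means rounded by the
field's reporting convention: nearest integer at ≥10, one decimal below
10. Regime changes are detected by exhaustive two-segment piecewise-linear
search over interior breakpoints (each segment ≥3 points) on the
replicate-mean curve, flagged when the two-segment fit beats the single
line's residual sum of squares by >20% — with a rounding-level floor on
the single-line RSS so an exactly linear profile is never flagged.

## Problem sizes and determinism

The default analyses run on the sizes above (12 supercooled + 5 glassy
spectra of 71 points; 25 time points × 3 replicates), which keep a full
pipeline run to a few seconds while leaving every estimator
over-determined. All stochastic steps take explicit integer seeds and the
pipeline writes every threshold into its run metadata; rerunning with the
same inputs and seed reproduces byte-identical tables.
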