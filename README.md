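# amorphkit

Dielectric-relaxation and dissolution analysis for amorphous pharmaceutical
solids.

Amorphous drug forms dissolve faster than their crystals but are metastable;
whether they stay amorphous depends on their molecular mobility, summarized
by the structural (α) relaxation time τ_α. Broadband dielectric
spectroscopy measures τ_α above the glass transition directly as the
frequency of the α-loss peak; below T_g the peak leaves the instrument's
window and τ_α must be inferred. `amorphkit` implements the standard
analysis chain used for such samples (e.g. vitrified vs cryomilled
bosentan), together with stationary-disc intrinsic-dissolution-rate
analysis, as a reusable, tested Python library with a CLI.

## What it computes

* **Havriliak–Negami fits per temperature** — the loss model
  ε″(ω) = σ_DC/(ε₀ω) − Im[Δε / (1 + (iωτ_HN)^a)^b],
  fitted in log₁₀(ε″) space with multi-start least squares
  (`amorphkit.hn_fit`).
* **α-relaxation times** — τ_α = τ_HN·[sin(πa/(2+2b))]^(−1/a)·[sin(πab/(2+2b))]^(1/a),
  the reciprocal angular peak frequency (`amorphkit.vft_analysis`).
* **KWW peak shape** — the one-sided Fourier transform of the stretched
  exponential φ(t) = exp(−(t/τ)^β), evaluated to ≤10⁻⁶ relative accuracy
  and fitted to the α peak to give β_KWW; a shape-invariance check across
  temperature validates time–temperature superposition (`amorphkit.kww`).
* **VFT extrapolation and T_g** — τ(T) = τ_∞·exp(B/(T−T₀)) fitted to the
  relaxation map; T_g defined as T(τ_α = 100 s) in closed form with
  propagated uncertainty (`amorphkit.vft_analysis`).
* **Master-curve prediction below T_g** — horizontal log-frequency shifts
  superposing flank-only glassy spectra onto a supercooled reference, giving
  predicted τ_α(T < T_g) and its deviation from the VFT extrapolation
  (`amorphkit.master_curve`).
* **Intrinsic dissolution rates** — IDR = (V/S)·dC/dt from windowed OLS
  slopes of replicate concentration–time curves, fold changes between
  samples, and piecewise-linear detection of kinetic regime changes
  (`amorphkit.dissolution`).
* **Synthetic data** — a generator producing VFT-governed spectrum ladders
  with temperature-invariant shape plus conductivity tails, flank-only
  glassy spectra, and first-order dissolution curves
  C(t) = C_s·(1 − exp(−kSt/V)) with replicate noise
  (`amorphkit.synthetic_data`), so every stage has a closed-loop recovery
  test.

## Worked example

```python
import numpy as np
from amorphkit import (SpectrumSet, SpectrumSimConfig,
                       simulate_spectrum_set, simulate_glassy_flanks)
from amorphkit.cli_pipeline import RunConfig, run_dielectric_pipeline

cfg = SpectrumSimConfig(noise_cv=0.01, seed=7)     # default VFT law: Tg(100 s) = 351 K
spectra = SpectrumSet(
    list(simulate_spectrum_set(cfg))
    + list(simulate_glassy_flanks(cfg, [342, 344, 346, 348, 350]))
)
report = run_dielectric_pipeline(spectra, RunConfig(outdir="run", seed=1))
print(f"Tg = {report.tg.tg:.2f} +/- {report.tg.uncertainty:.2f} K")
print(f"beta_KWW = {report.shape_result.betas.mean():.3f} "
      f"(spread {report.shape_result.spread:.3f})")
print(f"max |deviation| from VFT below Tg: {report.deviation.max_abs:.3f} decades")
```

prints (1% multiplicative noise, seed 7)

```
Tg = 350.88 +/- 0.10 K
beta_KWW = 0.619 (spread 0.014)
max |deviation| from VFT below Tg: 0.109 decades
```

The generating law has T_g = 351 K and β_KWW = 0.62: the pipeline recovers
the glass-transition temperature within a fraction of a kelvin, confirms the
peak shape is temperature-invariant, and the master-curve prediction tracks
the VFT extrapolation to ~0.1 decades ten kelvin below T_g.

The same pipeline runs from the shell:

```bash
amorphkit simulate spectra --seed 7 --out spectra.csv
amorphkit fit-hn --spectra spectra.csv --out hn.csv
amorphkit run-all --seed 7 --out run/
amorphkit idr --profile dissolution.csv --window 0 15
```

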