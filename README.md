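# dielpredict

Tools for asking whether the *predictability* of day–night (diel)
temperature and dissolved-oxygen cycles in coastal waters shapes the heat
tolerance of the marine ectotherms living there.

Productive shallow habitats warm and oxygenate together every day:
photosynthesis pushes dissolved oxygen above air saturation exactly when
temperature peaks. If that coupling is regular, animals may rely on oxygen
supersaturation to survive temperature maxima — so the *gain* in lethal
temperature under supersaturation (ΔLT50) should be largest for species
with the smallest thermal safety margins, living in the most predictable
environments. `dielpredict` implements the full analysis chain for testing
that hypothesis from raw logger records and thermal-ramp assays, plus a
synthetic-data generator with known ground truth for every stage.

## What it computes

**Diel predictability of a logger series.** Each regularized, detrended
(optionally percentile-transformed) series is decomposed with a Morlet
continuous wavelet transform (ω₀ = 6, Torrence–Compo conventions). Power at
each time *t* and Fourier period λ is tested pointwise against a red-noise
null: an AR(1) background spectrum

&nbsp;&nbsp;&nbsp;&nbsp;P(λ) = (1 − φ²) / (1 + φ² − 2φ cos(2π δt/λ)),

with φ the series' lag-1 autocorrelation and a χ²₂ 95% threshold. The
predictability index is the fraction of the record — outside the cone of
influence at the 24 h scale — with significant 24 h power, reported both
pointwise (% of time) and as a day count (days whose significant fraction
exceeds 50%, over all days with usable timestamps).

**Temperature–oxygen coupling.** Cross-wavelet power |W_T · W̄_DO| and
relative phase arg(W_T · W̄_DO) (positive phase = temperature leads), plus
full-resolution lagged Pearson correlations and the regression of daily DO
range on daily mean temperature.

**Thermal tolerance.** LT50 from checkpointed ramp mortality by
interval-censored maximum likelihood for a logistic death-temperature
distribution, parametrized logit(F) = β₀ + β₁T so LT50 = −β₀/β₁ with a
delta-method SE; ΔLT50 = LT50(140% O₂) − LT50(97% O₂); thermal safety
margin TSM = LT50 − mean daily maximum habitat temperature; and the OLS
regression of ΔLT50 on TSM across species.

**Path analysis.** A recursive path model on standardized species records
(fluctuation amplitudes and predictability → TSM → ΔLT50), fitted by
normal-theory maximum likelihood on the implied covariance
Σ = (I−B)⁻¹Ψ(I−B)⁻ᵀ, with χ² = (n−1)·F_ML, CFI, RMSEA, and a d-separation
(Fisher's C) test as a secondary criterion.

## Worked example

```python
import numpy as np
from dielpredict import (load_preset, diel_predictability, cross_wavelet,
                         detrend_linear, fit_lt50)
from dielpredict.synthetic import (EnvSimParams, simulate_env_pair,
                                   AssaySimParams, simulate_ramp_assay)

params = EnvSimParams(**{**load_preset("tropical"), "seed": 11})
temp, oxy = simulate_env_pair(params)

rep = diel_predictability(temp)
print(f"T—{rep.site_id}: {rep.n_days_significant}/{rep.n_days_total} days "
      f"({100 * rep.fraction_days:.0f}%)")
# T—tropical: 116/118 days (98%)

xw = cross_wavelet(detrend_linear(temp), detrend_linear(oxy))
i24 = int(np.argmin(np.abs(np.log(xw.period / 24))))
ok = (xw.coi_period >= 24) & (xw.sig_ratio[i24] > 1)
print(round(float(np.angle(np.mean(np.exp(1j * xw.phase[i24][ok])))), 3))
# 0.263   (oxygen trails temperature by ~1 h: 2π/24 ≈ 0.262 rad)

p = AssaySimParams(n_individuals=40, delta_super=2.0, seed=5)
full = fit_lt50(simulate_ramp_assay(p, "full_saturation"))
sup = fit_lt50(simulate_ramp_assay(p, "supersaturation"))
print(f"LT50 {full.lt50:.2f}±{full.se:.2f} vs {sup.lt50:.2f}±{sup.se:.2f}")
# LT50 34.90±0.32 vs 36.90±0.32   (ΔLT50 = 2.00 °C, the injected gain)
```

The tropical preset carries a diel signal on 90% of days; the index reads
back 98% of days here because significance at the 24 h scale has roughly
±1 day of temporal resolution, which merges near-adjacent quiet days (see
`docs/methods.md`).

A command-line interface mirrors the library:

```bash
dielpredict simulate env --preset tropical --seed 11 --out data/
dielpredict predictability --in data/tropical_env.csv --variable temperature
dielpredict xwt --temp data/tropical_env.csv --oxy data/tropical_env.csv --out out/
dielpredict run --config config.yaml     # full pipeline + manifest
```

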