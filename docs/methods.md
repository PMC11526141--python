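# Methods

## Environmental series handling

Logger records (temperature in °C, dissolved oxygen in % air saturation,
nominally every 10 min) are snapped onto an exact grid anchored at the
first timestamp. Internal gaps up to `max_gap` (default 6 h) are filled
linearly in time — or, optionally, by copying the value at the same clock
time from the nearest complete day (`strategy="nearest_day"`), which
preserves the diel shape through longer daytime dropouts; the nearest-day
dialect is off by default. Any gap beyond `max_gap` truncates the analysis
to the longest contiguous gap-free stretch, since the spectral machinery
assumes uninterrupted sampling. A requested grid step finer than ~2/3 of
the native sampling interval is rejected rather than silently upsampled.

Detrending removes a single least-squares line over the whole analysed
segment (no per-window detrending); at 10-min sampling a sinusoid spanning
integer cycles is not exactly orthogonal to a discrete line, so detrending
perturbs a pure diel tone by ~0.2% of its amplitude — negligible relative
to every tolerance used downstream. The percentile transform maps values
to average-rank/(n+1), bounded in (0,1) and tie-stable; it is applied by
default before wavelet analysis because it tames the heavy-tailed,
spike-prone distributions of productive-water oxygen records, at the cost
of discarding amplitude units (amplitudes are therefore measured by FFT on
the untransformed series).

Daily statistics (mean/min/max/range) use site-local calendar days and
require 80% of a day's expected samples; partial first/last days would
otherwise bias the min/max and hence the daily range.

## Wavelet machinery

The continuous wavelet transform uses the Morlet wavelet with ω₀ = 6, a
geometric scale grid s = s₀·2^(j·dj) with s₀ = 2δt and dj = 1/12, zero
padding to the next power of two, and power normalized by series variance
(white noise then has expected power 1 at every scale). The Fourier period
is λ = 4πs/(ω₀+√(2+ω₀²)) ≈ 1.033 s, and the cone of influence at distance
d samples from an edge is λ_COI = 1.033/√2 · d·δt — the e-folding distance
of edge artefacts. These are the standard geophysical-toolbox conventions.

Significance is pointwise: power is compared with the theoretical AR(1)
spectrum at the series' lag-1 sample autocorrelation (no bias correction)
scaled by χ²₂(0.95)/2. The sample autocorrelation of a finite non-constant
series is strictly below 1, so the "nonstationary" guard (φ ≥ 1) can only
trigger through an explicit `ar1_override`; strongly trending series
instead surface as very red nulls, which is the conservative behaviour.
Cross-wavelet significance multiplies the two AR(1) backgrounds and uses
the 95% cross-spectrum quantile constant for 2 dof (Z₂(0.95) ≈ 3.999).
Convention check: positive cross-wavelet phase at the 24 h scale means the
first series leads; a 1 h lag corresponds to 2π/24 ≈ 0.262 rad.

The 24 h amplitude is read from the FFT amplitude spectrum (2|X_k|/n) at
the bin nearest 1 cycle/day, linearly interpolated when 1 cpd falls between
bins; records must span ≥ 2 days.

## Predictability index

At the scale nearest 24 h (geometric distance; single scale, not a band
average — an 18–30 h band average changes Table-style fractions by a few
points and can be enabled for sensitivity analysis), each timestamp is
*valid* if its COI period reaches 24 h and *significant* if power exceeds
the red-noise threshold. Two statistics are reported: the pointwise
fraction of valid timestamps significant, and the fraction of days
significant, where a day counts if > 50% of its valid timestamps are
significant (threshold exposed; fraction_days is monotone nonincreasing in
it). Days with no valid timestamps are excluded from the denominator.

The wavelet at the 24 h scale averages over roughly ±1 day, so the index
has about a day of temporal resolution: isolated significant days bleed
into neighbours, and isolated quiet days inside long significant runs get
absorbed. Against backgrounds whose red-noise null is estimated from
realistically autocorrelated series (seasonal structure plus AR(1) noise)
the day-count recovers an injected diel-day prevalence to within a few
percentage points across the 0.2–0.9 range; with an artificially white
background (no slow structure at all) the lowered threshold lets the bleed
inflate low prevalences by up to ~20 points. Real logger series always
carry slow structure, but the index should be read as a ±1-day-resolution
measure, not a day-exact classifier.

## Thermal tolerance

Ramp assays observe each animal's death only between consecutive
checkpoints, so the likelihood is the exact interval-censored one: each
individual contributes P(death ∈ (T_{j−1}, T_j]) = F(T_j) − F(T_{j−1}),
with survivors past the last checkpoint contributing 1 − F(T_last). F is
logistic by default (probit available) with logit F = β₀ + β₁T, giving
LT50 = −β₀/β₁ and a delta-method SE from the numerically evaluated
observed information. The first interval is open on the left, so
extreme-tail deaths before the first checkpoint are handled without
special-casing. Optimization is Nelder–Mead from a moment start; when the
deaths are completely separated (all in one interval) the fit degenerates
and the estimate falls back to the bracketing-interval midpoint with the
half-width as SE and `convergence=False`. LT50 is exactly equivariant
under shifting all checkpoint temperatures.

TSM = LT50 − mean of the site's daily maximum temperatures, computed for
both oxygen treatments (the supersaturation variant is the ecologically
relevant one in productive habitats; the full-saturation variant can go
negative where habitat maxima exceed normoxic tolerance). ΔLT50 regressed
on TSM uses OLS with the F statistic, adjusted R² and the 95% CI of the
slope.

## Path model

Specifications use one statement per line (`y ~ x1 + x2`, `a ~~ b`); the
regression graph must be acyclic. Free parameters are the path
coefficients, one variance per variable (residual for endogenous, total
for exogenous) and the listed covariances. The normal-theory discrepancy
F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimized by Nelder–Mead polished with
BFGS, starting from per-equation OLS (the exact optimum for recursive
models with a saturated exogenous block — verified to 1e-6 in tests).
χ² = (n−1)·F_ML (Wishart convention, with S computed with n−1); CFI and
RMSEA follow the usual definitions with the independence model as
baseline; dof = p(p+1)/2 − free parameters, and a saturated model reports
RMSEA 0 with a note. Standard errors are from the inverse expected
information, (n−1)/2 times the numerical Hessian of F. No small-sample χ²
correction is applied — a caveat at n ≈ 17 species with 6 variables, where
fit indices are noisy and the χ² is only asymptotically calibrated.
Fisher's C (−2Σln pᵢ over the d-separation basis set, χ² with 2k dof) is
provided as a secondary ranking criterion alongside CFI/RMSEA ordering.

## Synthetic generator

`simulate_env_pair` builds T(t) = mean + seasonal sine (365 d) + a_d ·
diel cosine + AR(1) noise, where a_d ∈ {0,1} is drawn per day with
P = p_day: day-level on/off gating is the mechanism for tuning
predictability because the index counts significant days. Oxygen couples
to the *lagged temperature anomaly* (deviation from a centred 24 h running
mean), plus its own gated diel component and independent AR(1) noise,
clipped at 0% saturation. Defaults: 120 days at 10-min sampling, diel
amplitude 1.5 °C against AR(1) noise of sd 0.5 °C (φ = 0.7 per step),
seasonal amplitude 5 °C, coupling 5 %sat/°C with a 1 h lag — a regime in
the range of productive coastal sites. Three presets
(tropical / warm_temperate / cold_temperate) qualitatively span the hot,
strongly cycling regime through the cool, weakly cycling one. The
generator does not model tides (the real series show a secondary ~12 h
line), fouling drift, sensor quantization, or weather-band synoptic
variability; passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artefact of field data.

`simulate_ramp_assay` draws logistic death temperatures and records them
at the first checkpoint at or above them (the ramp must start ≥ 4 scales
below the true LT50). `simulate_species_table` draws correlated exogenous
predictability/fluctuation values through a Gaussian copula and generates
TSM and ΔLT50 from linear structural equations; the default ΔLT50
equation (intercept 2.68 °C, slope −0.087 per °C of TSM, residual sd
0.3 °C) sits in the empirically reported range for coastal ectotherms, so
regression and path-model recovery are tested at realistic effect sizes.

## Problem sizes and numerical choices

Simulation-based checks use 50 seeds for significance calibration
(n = 4096 per series), 5 seeds per prevalence level for day-gating
recovery (120-day series), 50 replicate assays (n = 200 animals) for LT50
recovery, 200 replicate 17-species tables for CI coverage, and 20
replicates (n = 500) for path-coefficient recovery — sizes at which
Monte-Carlo error is comfortably below each tolerance. Wavelet transforms
zero-pad to the next power of two; phase is wrapped to (−π, π]; variance
normalization uses the population variance of the analysed segment. Ties
in model comparison preserve input order.
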