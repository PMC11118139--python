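# Methods

This note documents the model, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## The tension chain and its conventions

The conversion from applied peak-to-peak voltage to membrane electrical
tension composes four steps (crossover frequency → membrane capacitance;
voltage → local field; field → transmembrane potential; potential → tension).
Absolute tensions depend on several conventions, each of which is a config
switch recorded in every output:

- **Crossover prefactor** (`conventions.crossover_prefactor`): the membrane
  capacitance is `c·σ_med/(2π r f_co)` with `c = √2` by default (the standard
  single-shell crossover result); `c = 2` is available. The choice rescales
  `C_mem` (hence all tensions) by a constant factor and cancels nowhere, so
  it is surfaced rather than hidden.
- **Voltage convention** (`conventions.voltage`): the local field uses the
  voltage amplitude `V_pp/2` by default; an rms option divides by a further
  √2. The transmembrane-potential expression is treated as an
  amplitude-domain phasor and its complex denominator is taken in modulus.
- **Field model**: the non-uniform electrode field is collapsed into
  `E = g·(V_pp/2)/d` with electrode gap `d = 10 µm` and a dimensionless
  geometry factor `g`. The default `g = 0.3` is a calibration, not a measured
  value: it places the modal rupture voltage of the default generator
  (r = 1.07 nm, k0 = 1e-13 s⁻¹) near 6.5 V_pp at the 0.05 V_pp/s rate, the
  regime in which such experiments operate.
- **Rate convention** (`conventions.rate`): because σ ∝ V², the tension
  loading rate under a linear voltage ramp varies in time. The default is
  the instantaneous (Evans-style local) rate `R_σ = (2σ/V)·R_V` evaluated at
  the characteristic rupture voltage; under a time-varying rate the
  most-probable-tension relation holds exactly with the local rate (the mode
  condition `k(t*) = (A/k_BT)·R_σ(t*)` follows from `f = kS`, `f' = 0`). A
  "secant" alternative (σ divided by time since ramp start) is provided for
  sensitivity analysis.
- **Unit reference for the intercept**: the logarithm in the Bell line needs
  a rate reference; `R_σ` is expressed in N m⁻¹ s⁻¹ against 1 N m⁻¹ s⁻¹.
  `k0` and `W0` are only reproducible together with this reference, which is
  echoed in `BellFitResult.conventions`.

Parameters with defaults (all exposed in the config): medium conductivity
6.0e-3 S/m (a 60 µS/cm DEP buffer) and permittivity 80; cytoplasm
resistivity 2 Ω·m and permittivity 80; membrane permittivity 5; temperature
298.15 K; attempt frequency 1e13 s⁻¹; cell radius 10 µm and crossover
frequency 20 kHz (population means). The cytoplasm/membrane dielectric
values and the temperature are textbook-typical rather than measured;
absolute tensions are therefore convention-dependent, while slopes-derived
pore radii are much less so (the radius enters as the square root of the
inverse slope).

## The reaction coordinate

The Bell exponent uses the pore *area* `A = πr²` as the reaction coordinate
conjugate to tension (tension × area = energy). The fitted slope is
`k_BT/A`, and the "critical pore radius" reported everywhere is `√(A/π)`.

## Stochastic rupture simulation

Rupture times are sampled by inverse-CDF on the numerically integrated
cumulative hazard: the hazard `k(t) = k0·exp(σ(t)A/k_BT)` is evaluated on a
uniform time grid (`dt = 0.01 s` default), integrated by the trapezoid rule,
and each cell's rupture time is the interpolated first crossing of its
exponential deviate; cells whose deviate exceeds the total integrated hazard
are censored. Two ramp modes exist: the experiment-faithful voltage ramp
(tension from the electrical chain, 2→10 V_pp) and an idealized
constant-tension-rate mode whose survival function is known in closed form,

    S(σ) = exp(−(k_BT k0/(A R_σ))·(e^{Aσ/k_BT} − 1)),

and serves as the independent oracle (Kolmogorov–Smirnov distance of the
empirical rupture-tension CDF at n = 1e4 is tested below 0.02).

**Grid-resolution guard.** A per-step rupture probability `k·dt < 0.1` is
enforced wherever the survival probability still exceeds 1e-4, and a
violation raises `GridResolutionError` rather than silently biasing the
sample. The criterion is deliberately restricted to the region where
survival mass remains: under a voltage ramp the hazard keeps growing
exponentially after the distribution is exhausted (reaching ~1e17 s⁻¹ by
ramp end in typical configurations), where the step size no longer affects
any sampled time. Hazard exponents are clipped at 700 to avoid float
overflow in that same irrelevant region.

**Distribution shape.** Under an exponentially growing hazard the rupture
tension follows a *reversed* Gumbel law (left-skewed): the sample mean sits
`γ·scale ≈ 0.577·k_BT/A` *below* the mode that the Bell relation describes.

## Rupture detection

The detector standardises each trace against its own baseline (frames with
applied voltage ≤ 2.5 V_pp by default, where brightness is flat) and reports
the voltage of the first frame that (a) exceeds
`baseline mean + k_sd·baseline sd` and (b) starts an `m_sustain`-frame
window whose mean also exceeds that threshold (defaults k_sd = 3,
m_sustain = 3). Requiring the window mean — rather than every frame of the
window — to clear the threshold is what keeps the detected voltage within
one frame of the true step at moderate jump sizes: with a jump of five noise
standard deviations each individual post-jump frame clears a 3-sd threshold
with only p ≈ 0.98, so an every-frame rule lets a single weak frame postpone
the detected onset (measured: 95% of detections within one frame, versus
99.5% for the window-mean rule, at 0.075% false positives on jump-free
traces). The standardisation makes detection invariant to intensity offset
and positive rescaling; ties go to the first qualifying frame; on noiseless
steps detection is exact and never precedes the jump. Known trade-off: one
isolated extreme glitch can carry the window mean; the optional 3-frame
median pre-filter (off by default) removes such glitches.

Zero baseline variance with no intensity increase is degenerate: the trace
is censored with a warning rather than an error.

## Aggregation and fitting

Per loading rate, censored cells are excluded (but counted) and the
characteristic rupture voltage is the **mean** by default, matching how such
experiments are usually summarised. Because the Bell relation is a modal
statement and the rupture law is left-skewed, a mean-based line recovers the
slope (pore radius) essentially unbiased but shifts the intercept by
`−γ·s`, biasing `W0` by about −0.6 k_BT. Two alternatives are provided: a
KDE-based **mode** estimator, and a **gumbel-corrected-mean**
(mean + γ·sd·√6/π, the reversed-Gumbel mean-to-mode offset estimated from
the sample sd), which is the estimator of choice when the barrier itself is
the quantity of interest.

The line fit is ordinary least squares of σ on ln R_σ (weighted least
squares by the per-point standard error is optional, off by default, since
such experiments are usually fitted unweighted). A non-positive fitted slope
is model-inconsistent data and raises an error instead of producing a
complex radius. Standard errors of r, k0, and W0 follow from the parameter
covariance by the delta method; bootstrap confidence intervals resample
cells within each rate (percentile intervals, seeded).

## The synthetic generator as a study design

Generator defaults emulate the experimental conditions: a 2→10 V_pp ramp at
41 kHz; six loading rates 0.003, 0.006, 0.012, 0.025, 0.05, 0.1 V_pp/s
(range and rate are primary, so the 0.05 V_pp/s ramp lasts 160 s); ~200
cells per run (500 per rate in recovery studies); 10 frames/s traces with
baseline 100, noise sd 2, and a jump of 10 grayscale units (5× noise) at
rupture. Population heterogeneity (radius 10 ± 1 µm, crossover 20 ± 2 kHz,
truncated to positive) is off by default so recovery tests isolate the
kinetics; switching it on at these spreads degrades but does not break
recovery (tested within 10% on the radius at 200 cells/rate).

Emulating a cholesterol-depletion series requires both a smaller pore and a
faster `k0`: with `k0` held at 1e-13 s⁻¹ a 0.58 nm pore's most probable
rupture tension (~0.11 N/m) exceeds the maximum tension the 2–10 V_pp ramp
can deliver (~0.08 N/m), and essentially every cell survives the ramp. The
generator therefore provides a modal-voltage calibration,
`k0 = R_σ(V*)·(A/k_BT)·exp(−σ(V*)A/k_BT)`, which places the modal rupture
voltage at a target (6.5 V_pp at 0.05 V_pp/s by default); conditions built
this way have coinciding rupture-voltage windows while their slopes — and
hence radii and barriers — differ, which is the experimentally observed
pattern. Note this means the generating barrier `W0 = ln(v0/k0)` of such
series (≈60 → 40 k_BT) is far larger than barriers quoted from experimental
intercepts under other conventions; `W0` is only meaningful jointly with the
attempt frequency and the rate reference recorded in the output.

## What the synthetic tests do and do not show

The traces emulate a step change in mean window brightness with additive
Gaussian noise; real micrographs have drift, cell motion, focus changes,
neighbour crosstalk, and image-segmentation error, none of which are
modelled — detection performance numbers here are upper bounds. The field
model replaces a finite-element electrode solution with one geometry factor,
so absolute tensions (and `k0`, `W0`) inherit that approximation; recovery
tests demonstrate the *inference machinery* is unbiased when the generating
model is true, not that the electrical model matches any particular chip.
No dielectric dispersion, Joule heating, or pore-expansion dynamics are
modelled; the maximum-likelihood fit of the full first-passage distribution
is deliberately out of scope (the linear Bell-line procedure is the method
under study, with closed forms as oracles).

## Problem sizes and determinism

Recovery studies use 6 rates × 500 cells with traces and detection (a few
seconds per condition); the simulator-oracle KS check uses 1e4 cells;
detector accuracy uses 1000 replicate traces; bootstrap intervals use
200–1000 resamples. Every stochastic step takes an explicit seed, a single
master generator derives per-stage child seeds, and identical seeds give
byte-identical datasets and reports.
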