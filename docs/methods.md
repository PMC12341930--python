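# Methods

## The consortium model

The package models an obligate mutualism between two *P. putida* strains,
CP-X (xylose eater, cellobiose cleaver) and CP-G (glucose eater, xylobiose
cleaver), as two coupled ODEs for the strain optical densities X(t) and G(t):

    dX/dt = (r_mx / α_Bx) · (α_Dg G / (C_g + G)) · (1 − (G + X)/(α_K K)) · X
    dG/dt =  r_mg         · (α_Dx X / (C_x/α_Ex + X)) · (1 − (G + X)/(α_K K)) · G

Assumptions baked into this form:

* **No explicit sugar states.** Substrate supply is represented implicitly:
  each strain's Monod-type factor saturates in the *partner's* density,
  standing in for the partner-supplied monosaccharide. The model therefore
  cannot describe transient substrate accumulation or depletion kinetics —
  HPLC-level questions are handled separately by the depletion estimator.
* **Shared logistic cap.** Both strains compete for one pooled resource
  budget (the carrying capacity K), scaled in scenarios by the most
  restrictive factor, α_K = min(α_Ex, α_Dx, α_Dg). The burden factor α_Bx
  slows CP-X but never caps the biomass, so it is excluded from the minimum.
* **Asymmetric burden.** Only CP-X carries an expression/degradation burden
  knob (α_Bx); no symmetric factor for CP-G is introduced, matching the
  engineered system where BglC expression dominates the cost.
* **Obligacy is exact.** Either strain at zero density freezes the whole
  system; there is no background growth term.

Units are fixed: time in hours, densities in OD600 units, rates in h⁻¹.
The reference parameter set (`BASELINE_PARAMETERS`) is
r_mx = 0.12 h⁻¹, r_mg = 0.34 h⁻¹, C_x = 0.04, C_g = 0.02, K = 0.82, fitted to
the reference cocultivation on 1 g/l of each disaccharide; all α default
to 1, which is the condition that fit was made under. Substrate scenarios
translate initial disaccharide amounts into α_Dx/α_Dg proportionally against
a 1 g/l-per-disaccharide reference.

## Numerical integration

`simulate` uses the adaptive explicit RK45 of `scipy.integrate.solve_ivp`
with rtol = 1e−8, atol = 1e−10; the system is only mildly stiff (two smooth
states, rates ≤ 0.34 h⁻¹), so an explicit method is adequate, which a
fixed-step RK4 oracle in the test suite confirms to 1e−5. Output OD values
are clipped at zero to remove round-off-level negative excursions; an
excursion below −1e−12 is treated as an integrator failure rather than
silently clipped. The default output grid is 0–72 h at 0.5 h, mirroring a
plate-reader protocol of half-hourly reads over 72 h; equilibrium checks use
300 h, by which the reference scenario is within 1e−6 of its capacity.

## Parameter fitting

The five parameters are estimated from the total OD and the deconvolved CP-X
OD (the two observables a calibrated plate-reader cocultivation yields) by
bounded least squares on the stacked residuals of both series, equally
weighted — neither series has a principled precision advantage after
calibration. Choices that were genuinely open:

* **Search strategy.** The objective is multimodal in the weakly
  identifiable C_x/C_g directions, so the fit is a multistart (default 8)
  trust-region-reflective solve in log10-parameter space; log space respects
  positivity and evens out the scale difference between rates (~0.1) and
  half-saturation constants (~0.01). The first start is the geometric
  midpoint of the bounds; the rest are seeded log-uniform draws, so a fit is
  deterministic given its seed.
* **Bounds.** r_mx, r_mg ∈ [1e−3, 2] h⁻¹; C_x, C_g ∈ [1e−4, 1] OD;
  K ∈ [0.05, 5] OD — generous brackets around biologically plausible plate
  cultivation values. Estimates landing on a bound are flagged.
* **Initial state.** Taken from the first observed time point (od_x, and
  total − od_x), floored at 1e−4 OD because read noise at inoculation-level
  densities can otherwise zero a strain and freeze the obligate model; a
  known inoculation state can (and, when available, should) be passed
  explicitly, which the CLI does from the config's scenario section.
* **Degenerate data.** A total-OD series with less than 10% relative range
  is rejected outright rather than fitted.

Identifiability, measured on synthetic data: the growth rates and K are
recovered to ~1% from noise-free data and to well under 10% median relative
error at 0.01 OD noise; C_x and C_g are weakly identifiable from OD-only
data (tested at a 50% band) because they only shape the early, low-signal
part of the curves. Conclusions about enzyme amounts drawn from fitted
C_x/C_g values should be treated as order-of-magnitude.

## Fluorescence calibration and deconvolution

Monoculture wells grown alongside each experiment give paired
(fluorescence, OD) points per strain. The calibration family is a continuous
two-segment curve — linear at low fluorescence, quadratic above a breakpoint
chosen by minimising in-sample error — with monotonicity enforced (candidate
fits whose derivative goes negative are discarded; a plain line is the
fallback). A raw relationship with Spearman ρ < 0.8 is rejected as
uncalibratable. Coculture deconvolution maps the GFP channel to CP-X OD
through this curve (out-of-range inputs are clamped to the boundary ODs and
flagged) and obtains CP-G as total − CP-X, clamped at zero with clamp events
counted. The direct mScarlet route is supported but not the default: the
red chromophore matures slowly, so its signal lags CP-G biomass, which the
synthetic generator reproduces as a first-order low-pass (default half-time
40 min) and which the subtraction rule sidesteps.

## Growth and conversion metrics

* **μ_max** — the largest slope of ln(OD) over a sliding window of 5 samples
  (2.5 h at the 0.5 h cadence), restricted to ODs above a 0.02 floor to
  suppress read noise; both knobs are configurable. Windowed log-slopes are
  the standard plate-reader estimator; no smoothing is applied first.
* **Lag** — the tangent convention (intersection of the log-space tangent at
  the μ_max window with the initial OD level) rather than a threshold
  crossing, because it is robust to the noise floor and standard in
  growth-curve analysis.
* **Conversion rate** — the magnitude of the least-squares slope of a
  disaccharide HPLC series over its depletion segment, which ends when the
  concentration first falls below 10% of its initial value; the cutoff
  avoids both the HPLC quantitation floor and the late-time evaporation
  artefact in which volume loss concentrates the remaining sugars. A series
  whose best-fit slope rises yields rate 0 with a `rising` flag.

## Synthetic data generator

The generator exists so every pipeline stage is testable without instrument
exports. It emulates: ODE-model trajectories observed as OD600 plus two
fluorescence channels (GFP proportional to CP-X, mScarlet first-order-lagged
behind CP-G, instrument yields defaulting to 1000 and 800 AU/OD — free
parameters, since real AU scales are gain-dependent); additive Gaussian
noise per channel; optional multiplicative evaporation drift,
(1 + rate)^(t − 48 h), after a default 48 h start; and HPLC series with
linear disaccharide depletion, the hydrolysis water-mass gain
(glucose: 360.32/342.30 per g cellobiose; xylose: 300.26/282.25 per g
xylobiose, from molar masses 342.30/180.16/282.25/150.13 g/mol), and linear
monosaccharide consumption, all clipped at zero. HPLC defaults (2 g/l
initial, 16 samples over 48 h) match a resting-cell depletion assay. All
generators are pure functions of their inputs and a seed.

What it deliberately does not emulate: instrument export formats,
chromatogram-level artefacts, well-position effects, cell clumping and
spatial structure, and any feedback from sugar concentrations onto growth
(the ODE model has no sugar states). Passing round-trip tests on this
generator therefore shows the pipeline is self-consistent under its own
noise model, not that the model captures every feature of real cultivation
data.

## Problem sizes

Default simulations run 145 output points (72 h at 0.5 h); fitting
experiments use 3 replicates of that grid at 0.01 OD noise, and the repeated
recovery study uses 20 single-replicate fits on an hourly grid with 3 starts
each — sizes chosen to match the plate protocol while keeping a full test
run in the low minutes. Conversion-rate recovery uses 16 points over 48 h at
0.02 g/l noise.

## Known limitations

* The model is phenomenological: α factors rescale a fitted baseline, so
  predictions far from the fitted condition (e.g. α ≫ 1) extrapolate.
* C_x/C_g are weakly identifiable from OD-only data (above); fitting the α
  factors themselves is intentionally unsupported — they are scenario
  inputs, not fitted quantities.
* Continuous cultivation (chemostat inflow), oxygen limitation and
  extracellular enzymatic conversion are out of scope.
* The calibration's functional form (two-segment linear/quadratic) is one
  reasonable member of the "combined linear or polynomial" family; only the
  monotone map itself, not its parameterisation, should be interpreted.
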