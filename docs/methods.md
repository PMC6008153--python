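# phoskit methods

## The measurement model

A closed, stirred incubation of volume ~1 mL holds a concentrated algal
suspension in artificial seawater of known salinity S, temperature T and
total alkalinity A_T. Over a 26-minute run the light steps through
0, 20, 50, 200, 500, 1000 and 2000 µmol quanta m⁻² s⁻¹ in 2-min periods,
each nonzero step followed by a 2-min dark recovery (the first dark period
is the respiration measurement). Because the run is short, A_T is treated
as constant: algal growth changes alkalinity on the scale of hours, and
CO₂ exchange does not change it at all. Under that assumption pH_T and DIC
determine each other through the carbonate equilibria, so the 1 Hz pH track
is a DIC track, and the per-period linear slope is a net carbon flux.
Oxygen rides along through the MIMS O₂/Ar ion-current ratio and a linear
two-point (air-saturated / dithionite-zeroed) calibration.

Key assumptions, in decreasing order of importance:

- constant A_T within a run (verified in practice by titrating before and
  after);
- instantaneous carbonate-system equilibrium (no CO₂ hydration kinetics);
- net fluxes only — respiration and gross photosynthesis are not separated;
- the pH electrode's liquid-junction offset is identical in Tris-buffered
  synthetic seawater and in the culture medium (this is what lets a single
  Tris measurement convert the NBS buffer scale to the total scale).

## Carbonate engine

All equilibrium math runs in mol kg⁻¹ on the total hydrogen-ion scale
([H⁺] = 10^(−pH_T)); the public API uses µmol kg⁻¹ and converts to
volumetric units through the medium density (default 1.0352 kg L⁻¹).
The default constant set (`constants = "lueker2000"`, pluggable via
`phoskit.carbonate.CONSTANT_SETS`) is the standard-practice combination:
K₁/K₂ from Lueker et al. (2000, total scale), K_B from Dickson (1990), K_W
from Millero (1995), phosphoric and silicic constants from the Millero
(1995) compilation. The phosphoric/silicic formulations are nominally on
the seawater scale; the ≲0.01-unit scale difference moves A_c by well under
0.1 µmol kg⁻¹ at incubation pH and is ignored. Total borate defaults to
Uppström boron scaled by S/35 and can be overridden for artificial media.

Carbonate alkalinity subtracts borate, hydroxide, phosphate (HPO₄²⁻,
2·PO₄³⁻, minus H₃PO₄) and silicate from A_T; the −[H⁺] closing term of the
full alkalinity definition is deliberately omitted in this incubation-range
expression (≤0.01 µmol kg⁻¹ above pH 7.5). The titration forward model uses
the full charge balance including −[H⁺], which it must to reach pH ~2.

`ph_from_dic` inverts DIC(pH) by bisection on pH ∈ [6, 10] to 10⁻¹⁰ pH —
robustness over speed, since the function is called once per trace sample
at most. The simulator replaces the per-sample bisection with a dense
(10⁻⁵-pH-step) monotone lookup table whose interpolation error (~10⁻⁸ pH)
sits far below the electrode noise floor.

### Gran titration

The Gran function F = (m₀+m)·10^(−pH) is fitted linearly against acid mass
over the acid-excess region, defined as pH_T < 3.8 (the classical window;
a configurable cut-off). The x-intercept gives the equivalence amount and
A_T = m_e·[HCl]/m₀. The forward model titrates an open cell: past the
equivalence point the stirred sample retains only 2% of its (diluted) DIC,
matching standard practice. Residual CO₂ is the factor that limits Gran
linearity — a fully closed cell would bias A_T low by several tenths of a
percent at this window.

## Calibration

- Electrode: OLS of buffer voltage on buffer pH; the slope must fall within
  [0.90, 1.05] of the ideal Nernst slope ln(10)RT/F (59.16 mV/pH at
  298.15 K, computed from physical constants so other temperatures
  generalize). 90% is the conventional glass-electrode rejection criterion.
- ADC resolution: (mV/bit ÷ amplifier gain) ÷ Nernst slope. At the
  instrument's 0.1875 mV/bit and 2.2 V/V this is 0.00144 pH per bit.
- Oxygen: Garcia & Gordon (1992) Benson–Krause combined fit for O₂
  saturation (check value 274.61 µmol kg⁻¹ at S=35, 10 °C); concentration
  from the O₂/Ar ratio by linear interpolation between the zero and
  saturation ratios. Supersaturated readings are valid (a photosynthesizing
  closed cell supersaturates). Common multiplicative drift on both channels
  cancels identically in the ratio.

## Rates and fits

Each 2-min segment is trimmed by 10 s at its start (electrode/membrane
response after a light transition; the transient-robustness test shows a
5-s transient then moves slopes by <1%) and the remaining ~110 points are
fitted by OLS. Rates are reported per mg Chla and hour:
rate = −slope(µmol kg⁻¹ s⁻¹)·density·3600/chla, uptake positive for carbon,
evolution positive for oxygen. Only the first dark period enters the P-vs-E
set; later dark periods are retained as drift QC.

The photoinhibition fit uses the respiration-offset procedure: R = |dark
rate| is added to all rates, the exponential saturation curve is fitted
(multistart Levenberg–Marquardt: α from the first two light points, P_max
from the maximum rate, β = 0, plus 5 seed-fixed jittered restarts), and R
is subtracted from the fitted curve. A negative fitted β is clamped by
refitting with β = 0. The hyperbolic-tangent form provides the
initial-slope α on the same offset rates.

## Optics and quantum yield

Whole-cell absorbance A(λ), 400–700 nm at 1 nm, becomes the
chlorophyll-specific absorption a*_ph(λ) = ln(10)·A(λ)/([Chla]·x). The
ln(10) is the decadic-to-natural conversion: the instrument reports decadic
absorbance while the absorbed-flux integral needs an absorption
coefficient. Absorbed photon flux is the trapezoidal integral of
a*_ph·E₀(λ); spectra are linearly resampled onto the finer grid when grids
differ (refinement changes the integral by <0.1%).

The lamp spectrum is a required optical input that the instrument's vendor
does not publish; the package ships a generic white-LED shape (450 nm InGaN
peak over a broad 560 nm phosphor band) as a synthetic stand-in, always
normalized to unit PAR integral before being scaled by the segment
irradiance, and replaceable by a measured spectrum in the config. Φ(E) is
evaluated from the fitted net curves on a 1 µmol-step irradiance grid
(fitted-curve mode is the default; raw per-segment mode is available by
evaluating `quantum_yield` on measured rates). Φ_max is the grid maximum —
for net rates with R > 0 this peak sits strictly above the lowest light,
which is why the peak definition, not the initial slope, is used. A
physical ceiling of 0.125 mol/mol (one O₂ per 8 quanta) raises a sanity
flag if exceeded.

The growth cross-check converts an exponential growth rate µ (h⁻¹) and a
POC:Chla ratio into a Chla-specific carbon uptake,
P_Chl = µ·(POC/Chla)·(1000/12.011) µmol C mg⁻¹ Chla h⁻¹, for comparison
with the pHOS estimate interpolated to the growth irradiance.

## QC and sensitivity

- Detection limit: replicate disagreement is scored per chlorophyll level
  with `detection_t`: each measurement's deviation from its replicate mean
  is divided by the standard error of the mean across the seven light
  levels (df = 6), and the mean |t| is fitted as a power law in Chla and
  intersected with the Student-t critical value (1.943 at df = 6, 95%).
  The SEM is set by the P-vs-E signal spread while the deviations are
  noise, so the score scales with instrument noise and falls with
  chlorophyll. The simulator models electrode noise only; real replicate
  scatter (handling, biology) is larger, so simulated detection limits are
  lower bounds, not the practical limit.
- PAR self-shading: fractional loss = e^(a·OD₇₅₀ − b) at the cuvette
  center; with the empirical a = 9.12, b = 5.61 the 10% ceiling corresponds
  to OD₇₅₀ ≈ 0.35–0.36, and configs above it trigger a warning.
- Sensitivity: the default perturbation families are A_T ±1% and a uniform
  ±0.01 pH offset (titration repeatability and calibration drift). Each
  perturbation reruns pH→DIC→rates→fit. A uniform pH offset rescales all
  rates almost multiplicatively, so ΔP_max% ≈ Δα%; the A_T response is
  sub-proportional because the borate correction does not scale with the
  perturbed A_T. On the zero-noise baseline (A_T = 1980.1 µmol kg⁻¹,
  starting pH 8.05) the package computes +1.06% per +0.01 pH and +0.72%
  per +1% A_T.

## The simulator

`simulate_trace` integrates the forward physics at 1 s Euler steps: net
carbon rate from the prescribed P-vs-E truth at the commanded light (dark →
−R), DIC drawdown at constant A_T, pH via the carbonate engine, oxygen
slaved to carbon by a constant photosynthetic quotient and emitted through
the linear O₂/Ar calibration truth. Euler at 1 s is exact for this model
because the rates depend only on the (piecewise-constant) light. Noise is
additive Gaussian on pH (electrode counts) and multiplicative Gaussian on
each ion-current channel (source/pressure fluctuation); traces are
bit-reproducible per seed. Defaults mirror the study conditions: S = 35,
25 °C, A_T = 1980.1 µmol kg⁻¹, starting pH 8.05, P_max = 154.79,
α = 1.11, β = 0, R = 10 µmol mg⁻¹ Chla h⁻¹, PQ = 1.2, Chla = 2 µg mL⁻¹,
σ_pH = 5×10⁻⁴.

What the simulator does **not** emulate: CO₂ hydration/dehydration
kinetics, carbon-concentrating mechanisms, within-run alkalinity drift,
correlated (1/f) MIMS drift, or biological replicate variability. Passing
recovery tests therefore demonstrate the correctness of the reduction
chain under the stated error model, not robustness to every failure mode
of real instruments.

Spectra: a*_ph is a three-Gaussian pigment-band model (Chla Soret 440 nm,
carotenoid 490 nm, Chla red 675 nm) scaled by a packaging factor ≤ 1
(intracellular self-shading lowers in-vivo specific absorption); the
absorbance spectrum is its exact inverse through the a* formula, so
spectral recovery is exact by construction.

## Numerical choices and edge cases

- Problem sizes: test and acceptance runs use single 26-min traces
  (1560 samples) and 20-scenario ensembles; the full suite runs in well
  under a minute.
- Bisection brackets: pH ∈ [6, 10] for incubations, [1.5, 10.5] for
  titration charge balance; out-of-bracket targets raise rather than
  extrapolate.
- Fits: `scipy.optimize.curve_fit` with bounds P_max, α > 0; tie-break β=0
  on negative photoinhibition; insufficient-data errors below 5 points
  (Platt) / 3 positive-light points (tanh).
- Degenerate inputs: zero-variance t-scores, equal O₂ calibration ratios,
  duplicate buffer pH, non-positive A_c, all-respiration Φ grids and
  non-monotone time axes all raise typed exceptions from
  `phoskit.errors`; large-but-usable anomalies (Tris offset > 0.5, Gran
  r² < 0.995, data gaps > 2 s, OD₇₅₀ above the ceiling) warn and proceed.

## Known limitations

- Surface pressure only; no pressure corrections to the constants.
- Only the (pH, A_T) and (DIC, A_T) input pairs are solved; this is a
  reduction pipeline, not a general CO₂-system calculator.
- The Φ computation is only as good as the lamp spectrum supplied; the
  shipped LED shape is a synthetic stand-in.
- Detection limits from the simulator reflect electrode noise alone (see
  above).
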