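# Methods

## Scope and model structure

The package models the primary drying phase of oral lyophilizates
freeze-dried in cold-form aluminium blister pockets, under the standard
quasi-steady assumptions of vial lyophilization modeling adapted to the
blister shape: a planar sublimation interface recedes from the top of
the frozen product to the pocket bottom; at every instant the interface
is in thermal and mass-flow equilibrium; the frozen layer conducts heat
one-dimensionally; and the dried cake above the interface resists vapor
flow with a resistance that depends only on the dried-layer thickness.
Freezing, secondary drying (bound-water desorption), radiation-explicit
heat transfer and batch variability are out of scope.

## Pocket geometry

The pocket is a sliced horizontal cylinder with spherical end caps.
From the chord *c*<sub>b</sub> and depth *h*<sub>b</sub> the slice radius
is R = (c²/4 + h²)/(2h); the frozen volume below a fill level L is a
spherical cap, π L²(3R − L)/3, plus the circular-segment area times the
cylindrical mid-section length L_cyl = L_b − c_b.  With L_cyl as the
segment multiplier the free-surface area π(c(L)/2)² + c(L)·L_cyl is the
exact derivative of the volume, which the test suite verifies against a
quadrature oracle to 10⁻⁶ relative.  An alternative `segment_mode="total"`
multiplies the segment by the full pocket length instead; it
overestimates the pocket volume by ~75% and is retained only so the two
conventions can be compared — the drying-time predictions reproduce the
reference values only with the cylinder-length convention, which is the
default everywhere.

Volume inversion (ice thickness from frozen volume) uses a bracketed
Brent solve on [0, h_b]; monotonicity guarantees a unique root, and the
round trip closes to < 10⁻⁹ m.

## Ice thermodynamics

Sublimation enthalpy uses the empirical correlation
ΔH(T) = α + βT − γT² + δ·exp(−(T/ε)²) (J/mol); the quadratic power of the
third term follows from the coefficient units (J/(mol·K²)) and matches
the Murphy & Koop sublimation-enthalpy values (51.08 kJ/mol at 0 °C)
where a linear term would not.  Vapor pressure over ice uses the Murphy &
Koop form P(T) = exp(α − β/T + γ ln T − δT), which reproduces the
611.657 Pa triple-point value within 0.2%.  Inside the simulator the
enthalpy is evaluated at the bottom product temperature (the bulk frozen
layer); a short inner fixed point resolves the ≤ 10⁻⁵-relative circular
dependence, and the sensitivity of any prediction to evaluating at the
interface temperature instead is far below 0.1%.

## Interface balance and time stepping

Given shelf temperature, chamber pressure and the layer thicknesses, the
interface temperature T_i solves: equilibrium vapor pressure at T_i
equals the chamber pressure plus the pressure excess needed to drive the
heat-limited sublimation flow through the dried-layer resistance, with
the frozen-layer temperature drop given by the empirical balance
ΔT = [a·L_ice·(P_i − P_c)/R_p − b·L_ice·(T_s − T_i)]/(1 − b·L_ice),
using the conversion factors a = 889 200 and b = 1.02 (1/m) exactly as
tabulated.  For a trial T_i the pressure excess and ΔT form a linear 2×2
system solved in closed form; the scalar residual is root-solved by
Brent's method on [210, 280] K to 10⁻⁶ Pa.  At the converged root the
energy–mass identity A_b·K_v·(T_s − T_b) = ṁ·ΔH/M holds to 10⁻⁸
relative (asserted in the tests).

Time stepping is explicit with Δt = 60 s (the tabulated simulation
resolution): the rate removes a frozen-layer volume ṁΔt/(θρ_ice) — the
porosity division because subliming the ice fraction frees the whole
cake layer — and the geometry inversion yields the new ice level.
Drying completes when the ice level reaches 10⁻⁷ m, with the completion
time linearly interpolated inside the final step; halving Δt moves
completion times by < 0.5%, and total sublimated mass closes the ice
balance to < 0.1%.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| c_b, h_b, L_b | 23.5, 7.2, 40.5 | mm | pocket chord, depth, total length |
| θ | derived from composition | – | cake porosity = water mass fraction |
| ρ_ice, ρ_sol | 918, 1018 | kg/m³ | ice and suspension densities |
| λ_ice | 2.3 | W/(m·K) | frozen-layer conductivity |
| K_v edge / center | (10.1917, 1.1408, 0.0614) / (12.7208, 0.3015, 0.0261) | see text | (α, β, γ) of K_v(P_c), 10–30 Pa |
| R_p high / low dose | (7.05×10⁴, 1.92×10⁸, −68.30) / (2.12×10⁵, 1.42×10⁸, −14.39) | m/s, 1/s, 1/m | (R_p0, A, B), fitted on L_dr ≤ 4.5 mm |
| T_c | −10 | °C | collapse temperature (upper limit for T_i) |
| machine limits | 1.4 °C/min, 0.1 °C, 30 s, 40 °C | | ramp, resolution, prediction interval, cap |

The high-dose porosity derived from the composition is 0.60775; the
tabulated rounded value is 0.6079 (0.03% apart, negligible everywhere).

## Traditional protocol ramp

The traditional cycle is a ramp from −30 °C to a −10 °C hold at 10 Pa.
The package defaults to a 0.25 °C/min ramp — the conservative rate used
by the experimental cycles this model was built around — which predicts
5.76 h for the high-dose product.  The prediction is ramp-sensitive:
at the 1.4 °C/min machine maximum it drops to 5.40 h (−6.3%), so the
acceptance tests scan 0.25–1.4 °C/min and document the spread rather
than assuming insensitivity.

## Dynamic optimization

Every 30 s prediction interval the controller enumerates the setpoints
reachable from the previous one (±0.7 °C in 0.1 °C steps, clipped to the
absolute bounds), evaluates each candidate with the edge-population K_v
— both at the current state and, advancing one interval, at the
end-of-interval state, so the constraint check does not lag the rising
cake resistance — invalidates candidates whose interface temperature
exceeds T_c, and commits the feasible candidate with the highest
sublimation rate (ties toward the colder setpoint).  When *no* candidate
is feasible the controller cools at the machine maximum and flags the
interval.  For the high-dose product this actually happens: near 2.1–2.6
mm dried thickness the shelf-temperature descent required to hold
T_i = T_c exceeds 1.4 °C/min, and the edge interface overshoots the
collapse limit by ≤ 0.14 K for about 12 minutes.  No greedy controller
under these machine limits can avoid the episode (one-interval lookahead
already halves the overshoot from 0.31 K); it is reported honestly in
`OptimizationResult.constraint_violated` and is far below the 2 °C
resolution at which collapse temperatures are determined.  The committed
staircase trajectory is then executed for the center population at the
60 s simulation resolution; that center ice-exhaustion time (2.66 h for
the high-dose product, a 54% reduction versus the traditional 5.76 h) is
the nominal primary-drying duration.  A 1 h terminal hold for hardware
execution is reported as metadata and excluded from the nominal time.

## Synthetic data generator

The generator produces the two experiment types the estimators consume,
as pure functions of (spec, seed).

*Gravimetric runs* fill pockets with 2.3 mL of water (porosity 1,
solution density 1000 kg/m³), draw each blister's true K_v around the
population model with 10% relative dispersion (emulating the large
blister-to-blister contact variability), simulate a −30 → −15 °C ramp
and 2.5 h hold with a tiny constant dried-layer resistance (10³ m/s —
open-ice sublimation is essentially resistance-free), and emit the
noisy sublimated mass (σ = 1 mg) and bottom-temperature trace
(σ = 0.1 K).

*Process traces* forward-simulate the conservative resistance-
characterization cycle (−30 → −25 °C over 30 min, hold; 2.5 mL of the
high-dose suspension; center K_v) against the truth R_p(L_dr) law.  The
frozen-layer temperature drop uses the Fourier-conduction closure — the
same relation the estimation pipeline inverts — so that at zero noise
the pipeline recovers the generating R_p coefficients to better than 1%
(the residual is the half-step bias of the cumulative-volume sum).  The
synthetic Pirani channel reads P_cap·(1 + 0.6·s(t)) with s the
normalized sublimation rate, a generator convention (not an instrument
model) that makes the pressure ratio decay to one at the endpoint.

What passing these tests shows — and does not.  The round trips prove
the estimation pipelines are exact inverses of the stated model at the
stated noise; they do not validate the model against a real dryer, where
shelf-fluid lag, radiation asymmetry and freezing-history variation in
R_p are not emulated.  Two identifiability findings from the recovery
studies are themselves informative: (i) the individual (α, β, γ) of the
K_v pressure model sit on a likelihood ridge and are not recoverable to
5–10% from five pressure levels at realistic noise, although the fitted
K_v(P) curve — the quantity the simulator consumes — recovers to ~2%;
(ii) with realistic thermocouple noise the R_p intercept scatters
strongly (early points divide by near-zero rates) while the mid-range
resistance is robust.  Tests assert the recoverable quantities.

## Endpoint detection

The Pirani/capacitance ratio detector estimates its two plateau levels
as medians of the first and last 10% of the trace and returns the first
linear-interpolated crossing of the halfway level; plateaus closer than
2% relative raise a no-endpoint error.  On the conservative synthetic
cycle the ratio decays gradually (it tracks the slowly falling
sublimation rate), so noise shifts the detected midpoint by tens of
minutes on a ~25 h run — the detector is sample-accurate only when the
decay is sharp.

## Numerical choices

Root solves: Brent, brackets [0, h_b] (geometry, xtol 10⁻¹³ m) and
[210, 280] K (interface).  Nonlinear fits: `scipy.optimize.curve_fit`;
the K_v fit is inverse-variance weighted and constrained to the physical
branch (α, β, γ ≥ 0), the R_p fit is unweighted (the estimation
procedure gives no variance model), truncated to L_dr ≤ 4.5 mm where
thermocouple-derived curves are trustworthy, and constrained to keep
1 + B·L_dr > 0 on the fit range.  Negative sublimation rates are clipped
(rate trace) or the points dropped (resistance pipeline, where the
definition is singular); counts are logged.  All internal units are SI;
configuration files may tag values with mm/mL/°C units, converted at the
boundary.
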