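# blisterdry

Mechanistic modeling and dynamic optimization of the **primary drying
phase** of oral lyophilizates — orally disintegrating tablets (ODTs)
freeze-dried directly inside cold-form aluminium blister pockets.

Freeze-dried ODTs are made by dosing a drug suspension into a blister
pocket, freezing it, and subliming the ice under vacuum.  Primary drying
dominates the cycle time, and the blister pocket is not the cylindrical
vial that classical lyophilization models assume: it is a **sliced
horizontal cylinder with spherical end caps**, so the sublimation area
shrinks as the ice front recedes.  This package is aimed at
pharmaceutical process modelers who want to characterize such a process
from standard experiments and shorten it without risking product
collapse.

## The model

Heat reaches the product through the shelf with an effective
heat-transfer coefficient *K*<sub>v</sub>, estimated gravimetrically:

> *K*<sub>v</sub> = *m*<sub>sub</sub> Δ*H*<sub>sub</sub> / (*A*<sub>b</sub> *M* ∫(*T*<sub>s</sub> − *T*<sub>b</sub>) d*t*),

and regressed against chamber pressure as
*K*<sub>v</sub>(*P*<sub>c</sub>) = (α + β*P*<sub>c</sub>)/(1 + γ*P*<sub>c</sub>),
separately for edge and center blister populations.  Vapor escaping
through the already-dried cake sees a resistance
*R*<sub>p</sub>(*L*<sub>dr</sub>) = *R*<sub>p0</sub> + *A* *L*<sub>dr</sub>/(1 + *B* *L*<sub>dr</sub>),
estimated from thermocouple traces by inverting the heat balance and the
pocket geometry.  During simulation, each time step solves the
quasi-steady interface balance for the sublimation-front temperature
*T*<sub>i</sub> — equilibrium ice vapor pressure at the interface, heat
conduction through the frozen layer, and vapor flow through the dried
layer — then advances the front through the pocket geometry.

The optimizer re-selects the shelf setpoint every 30 s within the
machine's ramp/resolution/cap limits, maximizing the sublimation rate
while keeping the edge-population interface below the collapse
temperature *T*<sub>c</sub>; the slower center population defines the
total drying time.

## Worked example

Two bundled reference configurations (`paper_highdose`, `paper_lowdose`)
pin the full printed parameter set of a 500 mg acetaminophen ODT (1.52 mL
fill, porosity 0.608) and its low-dose counterpart.  Simulating the
traditional cycle — shelf ramped from −30 °C to a −10 °C hold at 10 Pa —
for the high-dose product:

```sh
$ blisterdry simulate --out trace.csv
primary drying complete at 5.764 h (0.940 g sublimated)
```

The 0.940 g is the ice fraction of the frozen 1.52 mL fill; the trace CSV
holds the shelf, bottom and interface temperatures, the interface
pressure, the ice/dried layer thicknesses and the sublimation rate at
every 60 s step.  Dynamic optimization of the same product:

```sh
$ blisterdry optimize --out trajectory.csv --report report.json
optimized trajectory: edge dry at 2.341 h, center dry at 2.661 h (max edge T_i -9.86 degC)
```

The trajectory rises at the maximal 1.4 °C/min to the 40 °C machine cap,
plateaus, and then backs off as the growing cake resistance pushes the
interface toward the −10 °C collapse limit.  Drying the center population
in 2.66 h instead of 5.76 h cuts primary drying by 54%.  The report also
records the constraint margin: for this product the required cooling
briefly exceeds the machine ramp near 2.5 mm dried thickness, so the
interface overshoots the limit by 0.14 K for a few minutes — flagged as
`constraint_violated` rather than hidden.

The same library surface is available from Python
(`load_reference_config`, `simulate_protocol`, `optimize_trajectory`),
and `blisterdry synth` generates gravimetric runs and process traces with
known ground truth for testing the `fit-kv` / `fit-rp` / `endpoint`
estimation workflows end to end.

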