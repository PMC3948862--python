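# osmodyn

Dynamics of osmotically driven pressure generation in membrane-bound
compartments.

Plants pressurize their cells (turgor) by holding osmolytes behind a
semipermeable membrane; the same principle drives engineered osmotic
pressure generators — e.g. a restrained dialysis cassette filled with
concentrated PEG solution that, simply upon submersion in water, builds
tens to hundreds of kPa and can actuate devices or pump fluid for days
with no external power. Steady-state osmotic theory says nothing about
*how fast* such a compartment pressurizes; the transient is governed by
a non-obvious interplay of membrane area-to-volume ratio, hydraulic
permeability, volume expansion, solute dilution, fluid compressibility,
and membrane fouling. `osmodyn` is a simulator and calibration toolkit
for exactly that transient, for researchers modelling plant turgor
dynamics or designing osmotic actuators, pumps, and pressure sources.

## Model

Water flux across the membrane follows J_v = L_p(σΔΠ − ΔP) with
L_p = L_p0(1 − f(c)) (Hill-type fouling f), and the compartment absorbs
influx through its compliance dV/dP and fluid bulk modulus K, giving

    dP/dt = ρ_s · A · L_p0(1 − f(c)) · (σ ΔΠ(c) − P)
            ────────────────────────────────────────,   c = n / V(P)
                ρ_atm · (dV/dP + V(P)/K(c, P))

which `osmodyn` integrates with adaptive Runge–Kutta (dense output,
event detection for "time to gain X kPa"). Constitutive laws — van 't
Hoff or cubic Π(c), Hill fouling, quadratic-in-c / linear-in-P bulk
modulus, and constant / affine / exponential-log (plant cell wall) /
tabulated pressure–volume relations — are composable, and calibration
routines reduce bench measurements (osmometry pairs, volume-delivery
permeabilities, pumping runs, wave-speed data, pressure traces) to
model parameters, including a least-squares fit of the effective
membrane area to an experimental pressure trace. See
`docs/methods.md` for the full treatment.

## Worked example: a plant motor cell

The `pulvinus_1MPa` preset is a pulvinus extensor cell
(L_p0 = 3.6×10⁻¹⁴ m Pa⁻¹ s⁻¹, A = 2.02×10⁻⁸ m², V ≈ 3.23×10⁻¹³ m³,
cell-wall volume law V = v_ref·exp(1.06×10⁻⁶ P + 0.047 ln P)) that is
suddenly presented with a 1 MPa osmotic gradient:

```
$ osmodyn events --preset pulvinus_1MPa --gains 10e3,50e3 --out ev.csv
gain 10000 Pa: 317.863 s (5.298 min)
gain 50000 Pa: 468.489 s (7.808 min)
```

The cell gains 10 kPa of turgor in ~5 minutes and 50 kPa in ~8 minutes
— threefold faster than a desk-scale dialysis-cassette generator,
because its area-to-volume ratio is ~6×10⁴ m⁻¹. Dilution matters: the
cell swells as water enters, so the pressure asymptote
(`equilibrium_pressure`, ≈ 370 kPa here) sits well below the initial
1 MPa gradient.

The full trajectory (pressure, volume, concentration, osmotic gradient,
effective permeability, influx, stored energy) goes to CSV with:

```
$ osmodyn simulate --preset pulvinus_1MPa --t-end "10 min" --out ts.csv
wrote ts.csv (512 points, final P = 94592 Pa)
```

In Python, the same in three lines:

```python
import osmodyn as od
ts = od.simulate(od.preset("pulvinus_1MPa"))
print(od.time_to_pressure_gain(od.preset("pulvinus_1MPa"), [50e3]))
```

Other subcommands: `presets` (list shipped scenarios), `fit-area`
(fit membrane area to a measured trace), `calibrate-pi` /
`calibrate-fouling` / `lp0-pump` (constitutive-law calibrations),
`synth-trace` (seeded synthetic traces for estimator studies). A
commented configuration example is in `examples/run.yaml`.

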