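# Methods

## Model

`osmodyn` simulates the transient build-up (or release) of hydrostatic
pressure in a closed compartment bounded by a semipermeable membrane — a
plant motor cell, or an engineered osmotic pressure generator such as a
restrained dialysis cassette filled with aqueous PEG-4000.

Water crosses the membrane at the volumetric flux

    J_v = L_p (σ ΔΠ − ΔP),

with hydraulic permeability `L_p` (m Pa⁻¹ s⁻¹), reflection coefficient
σ (fixed at 1: the solute is fully retained), osmotic gradient
ΔΠ = Π_in(c) − Π_ext, and hydrostatic gradient ΔP = P_in (the external
bath is at 0 gauge). The influx must be accommodated by the compartment
either by expanding (compliance dV/dP of the pressure–volume relation
V_in(P_in)) or by compressing the fluid (V/K, with bulk modulus K).
Writing the mass balance with solvent density ρ_solvent entering and
working-fluid density ρ_atm stored, and linearizing the compressive
storage under K ≫ P_in, gives the governing equation integrated by
`dynamics.simulate`:

    dP/dt = ρ_solvent · A · L_p0 (1 − f(c)) · (σ ΔΠ(c) − P)
            ───────────────────────────────────────────────
                   ρ_atm · (dV/dP + V(P) / K(c, P))

The solute amount n is constant in the closed modes, so the
concentration c = n / V(P) falls as the compartment swells: volume
expansion simultaneously dilutes the driving force and absorbs influx,
which is why compliant compartments pressurize far more slowly than
rigid ones of the same area-to-volume ratio.

`mass_conservation_error` cross-checks the K ≫ P approximation by
comparing the stored mass ρ_atm (1 + P/K) V(P) against the
time-integrated membrane influx; on all shipped scenarios the mismatch
stays below 10⁻³ relative (it scales like P/K ≈ 10⁻⁴).

## Constitutive laws

* **Osmotic pressure.** Van 't Hoff, Π = φ c R T, for small osmolytes
  (plant sap); or a zero-intercept cubic Π = a₁c + a₂c² + a₃c³ for
  polymer solutions, whose osmotic response is strongly super-linear.
  The shipped cubic coefficients (a₁ = 1427.5 Pa/(mol m⁻³),
  a₂ = 202.42, a₃ = 5.8310 in the corresponding powers) are a
  least-squares fit to the four bundled PEG-4000 osmometry pairs
  (30, 50, 70, 125 mM → 0.38, 1.31, 3.09, 14.73 MPa); the fit reproduces
  every input pair within 0.7%. `calibration.fit_pi_cubic` performs the
  same fit on user data.
* **Fouling.** PEG binds to membrane pores, so the effective
  permeability is L_p = L_p0 (1 − f) with f(c) a Hill curve
  f_max c^h / (c_half^h + c^h). No fouling coefficients are shipped —
  they are strongly membrane- and solute-specific — so the default is a
  clean membrane (f ≡ 0) and `fit_fouling_hill` calibrates from
  (c, L_p,eff) pairs. Plant scenarios use f ≡ 0 on physical grounds
  (ionic/sugar osmolytes do not foul the cell membrane this way).
* **Bulk modulus.** K(c, P) = k₀ + k₁c + k₂c² + k_P·P. Default: pure
  water, k₀ = 2.2 GPa, other coefficients 0, overridable after
  calibration (`bulk_modulus_from_wave_speed`, K = ρ v², rigid-conduit
  assumption — conduit-compliance corrections are out of scope).
* **Densities.** ρ_solvent = 998 kg m⁻³ (water). ρ_atm is affine in the
  *initial* concentration with default slope 0.17 kg m⁻³ per mol m⁻³,
  a typical aqueous-PEG densification; it is held fixed over a run.
  Plant presets set the slope to 0 (dilute sap ≈ water).
* **Pressure–volume laws.** `constant` (rigid), `affine`
  (V = V₀ + γP, compliance γ), `plant_exp_log`
  (V = v_ref · exp(αP + β ln P), from bulk elastic modulus data of motor
  cells; requires P > 0), and `tabulated` (monotone piecewise-linear,
  no extrapolation, strictly increasing P and V so dV/dP is defined and
  positive).

## Scenario modes

* **pressurize** — closed compartment, osmotic influx against its own
  growing pressure; `equilibrium_pressure` solves Π(n/V(p)) = p for the
  asymptote (dilution makes it lower than Π(c₀) whenever dV/dP > 0).
* **depressurize** — the stimulated-release protocol of plant motor
  cells: ΔΠ is forced to zero for all t (instantaneous osmolyte
  equilibration) and the compartment drains against its own turgor.
  Solute tracking is disabled in this mode.
* **deliver** — open outlet at ~0 gauge: influx Q = A L_p σ Π(c) is
  expelled, and the solute washes out with the displaced fluid
  (dn/dt = −cQ), so delivery is concave in time; a non-dilutable-solute
  switch gives the constant-rate limit.

## Numerical choices

* Adaptive RK45 (`scipy.integrate.solve_ivp`), rel_tol 10⁻⁸, abs_tol
  10⁻⁴ Pa, dense output. The ODE is non-stiff at all shipped
  parameterizations. The abs_tol is set well below the 1 Pa starting
  pressure of the plant scenarios so that low-pressure transients are
  resolved to better than 10⁻⁴ relative; a fixed-step RK4 oracle at
  dt = 10 ms agrees with the adaptive solution to that level in the
  tests. Everything is deterministic; the only RNG in the package is the
  synthetic-trace generator, which is seeded explicitly.
* Trajectories are reported on ≥ 200 evenly spaced points; stored
  energy ∫P dV is accumulated by the trapezoid rule on that grid (exact
  for the affine law, where P is linear in V).
* Threshold-crossing times ("time to gain X kPa") are located on the
  dense output by Brent bracketing, so event accuracy does not depend
  on step placement.
* The plant volume law is singular at P = 0 (β ln P); plant scenarios
  start at a documented floor of p_initial = 1 Pa.
* Area fitting minimizes RSS(A) = Σᵢ (P_model(tᵢ; A) − Pᵢ)² by bounded
  Brent search; the model curve is evaluated on the trace's own grid
  from dense output. A minimizer within 0.1% of a search bound is
  flagged non-converged. RSS(A) is unimodal over a 10× bound range on
  the shipped scenarios (verified by grid scan in the tests).
* Meniscus speed in the pumping reduction is an OLS slope over all
  samples (noise-robust), not pairwise differences.

## Presets

* `pulvinus_1MPa` / `pulvinus_1p98MPa` — motor (pulvinus extensor)
  cell: L_p0 = 3.6×10⁻¹⁴ m Pa⁻¹ s⁻¹, A = 2.02×10⁻⁸ m²,
  v_ref = 3.23×10⁻¹³ m³, α = 1.06×10⁻⁶ Pa⁻¹, β = 0.047, van 't Hoff
  osmolytes with the solute amount set so the initial gradient is 1 MPa
  (or 1.98 MPa — the value implied by ~1000 mOsm/kg active sap; the
  1 MPa preset is the one whose dynamics the headline timings quote).
* `cassette_3ml_3p5kDa`, `cassette_3ml_2kDa`, `cassette_30ml_3p5kDa` —
  dialysis-cassette generators: L_p0 = 6.26×10⁻¹³ (3.5 kDa MWCO) or
  1.70×10⁻¹³ m Pa⁻¹ s⁻¹ (2.0 kDa), membrane area 21.9 cm² (3 mL) or
  60.0 cm² (30 mL), nominal fill volume, 70 mM PEG-4000, cubic Π.
  Measured initial volumes in practice run 1.5–2× the nominal fill
  (cassette dead volume and overfill), which lowers the initial A/V
  ratio to ~400 m⁻¹; override `moles_solute`/`v_ref` per experiment.
  The cassette presets default to a rigid volume law and a clean
  membrane because neither the measured cassette compliance curves nor
  the fouling coefficients are published; with those defaults they
  pressurize in seconds rather than the tens of minutes observed on the
  bench, where fouling (f ≳ 0.9 at working concentrations) dominates.
  `affine_cassette` swaps in a placeholder compliance of
  γ = 2×10⁻¹¹ m³ Pa⁻¹ (~1 mL of expansion at 50 kPa) for studies that
  need a compliant compartment; it is a stated stand-in, not a
  calibrated value.

## Synthetic traces, and what the tests do and do not show

`synth_pressure_trace` samples a simulated trajectory at evenly spaced
times and adds i.i.d. Gaussian noise — it emulates transducer noise
only, not drift, discretization, bubble artifacts, or model mismatch
(area change under bulging, membrane stretch, σ < 1 leakage). Parameter
recovery results on such traces (area to 0.1% noiseless / 2% at 0.2 kPa
noise; Hill parameters to 1% noiseless) therefore demonstrate the
correctness and conditioning of the estimators, not the accuracy
attainable on bench data, where the fitted area absorbs all model error
and varies within about a factor of two between repeat runs.

## Limitations

* Concentration polarization is neglected (appropriate for dialysis
  membranes at these fluxes) and σ is fixed at 1; slow solute leakage
  through high-MWCO membranes is outside the model.
* ρ_atm is frozen at its initial-concentration value rather than
  tracking dilution; the induced error is bounded by the fractional
  density change (< 2% at the shipped concentrations).
* Temperature enters only as a constant in the van 't Hoff law.
* Single solute; no multi-component mixtures or non-aqueous solvents.
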