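# Example run configuration for `osmodyn simulate --config run.yaml`.
#
# A scenario is either a shipped preset plus scalar overrides, or a fully
# inline specification (see the commented block at the bottom).
# Units: pressures Pa (gauge), concentrations mM (== mol m^-3 for aqueous
# solutions), times in seconds or with an explicit s/min/h suffix.

scenario:
  preset: cassette_3ml_3p5kDa
  overrides:
    concentration_mM: 125      # working-fluid PEG-4000 concentration
    t_end: "30 min"
    # lp0: 6.26e-13            # clean-membrane permeability, m/Pa/s
    # area_cm2: 21.9           # effective membrane area
    # p_initial_Pa: 5.0e3      # starting gauge pressure
    # mode: deliver            # pressurize | depressurize | deliver

outputs:
  timeseries: timeseries.csv   # columns: time_s, pressure_Pa, volume_m3,
                               #   conc_mol_m3, delta_pi_Pa, fouling, lp_eff,
                               #   influx_m3_s, delivered_m3, energy_J
  events: events.csv           # columns: gain_Pa, time_s, reached

report_points: 512
log_level: INFO

# Fully inline scenario (replace the `preset:` block above with this):
#
# scenario:
#   inline:
#     fluid:
#       concentration_mM: 70
#       osmotic_law: {mode: cubic_polynomial, a1: 1427.5, a2: 202.42, a3: 5.831}
#       fouling_law: {f_max: 0.0, c_half_mM: 1.0, hill_n: 1.0}
#       bulk_law: {k0: 2.2e9}
#     membrane: {lp0: 6.26e-13, area_cm2: 21.9, sigma: 1.0, mwco_label: "3.5 kDa"}
#     volume_law: {variant: affine, v_ref_ml: 3.0, compliance: 2.0e-11}
#     mode: pressurize
#     p_initial_Pa: 0.0
#     t_end: "30 min"
#     events_Pa: [10.0e3, 50.0e3]
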