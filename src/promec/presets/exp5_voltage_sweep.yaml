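# External-voltage sweep: 0.5-1.1 V; efficiencies pinned to the 0.8 V
# feasibility values so the grid varies only the electrical driving force.
pro:
  feed_volume_mL: 600
  feed_pi_bar: 2.4
  feed_substrate_mg_L: 193
  draw_molarity_M: 0.8
  draw_volume_mL: 600
  pressure_policy: half_delta_pi
  flux_stop_LMH: 0.5
  t_max_h: 48.0
mec:
  voltage_V: 0.8
sweep:
  variable: voltage
  grid: [0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1]
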