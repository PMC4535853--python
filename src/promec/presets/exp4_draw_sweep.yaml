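# Draw-concentration sweep: NaCl molarity 0.1-2.0 M.
pro:
  feed_volume_mL: 600
  feed_pi_bar: 2.4
  feed_substrate_mg_L: 193
  draw_molarity_M: 0.8
  draw_volume_mL: 600
  pressure_policy: half_delta_pi
  flux_stop_LMH: 0.5
  t_max_h: 96.0
mec:
  voltage_V: 0.8
sweep:
  variable: draw_molarity
  grid: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
         1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9, 2.0]
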