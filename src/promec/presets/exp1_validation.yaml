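# Constant-pressure validation run: 0.8 M draw, 1 bar, 6 h fixed duration.
pro:
  feed_volume_mL: 600
  feed_pi_bar: 2.4
  feed_substrate_mg_L: 193
  draw_molarity_M: 0.8
  draw_volume_mL: 600
  pressure_policy: constant
  P_bar: 1.0
  flux_stop_LMH: 0.0
  t_max_h: 6.0
mec:
  voltage_V: 0.8
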