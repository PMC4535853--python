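# Influent-volume sweep: feed and draw volumes varied together, 100-2000 mL.
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
  variable: pro_influent_volume
  grid: [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000,
         1100, 1200, 1300, 1400, 1500, 1600, 1700, 1800, 1900, 2000]
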