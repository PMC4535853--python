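# System feasibility: maximum-power pressure schedule P = (pi_D - pi_F)/2,
# 0.5 LMH flux stop, MEC at 0.8 V powered by the harvested osmotic energy.
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
coupling:
  use_pro_energy_budget: true
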