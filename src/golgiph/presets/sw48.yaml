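# SW-48 colorectal carcinoma preset (high exchanger density).
compartment:
  volume_fl: 10.0
  surface_area_um2: 600.0
  buffer_capacity: 40.0
  ph: 6.5
  cl_mM: 4.0
  hco3_mM: 2.0
  co2_mM: 1.5
params:
  pump_vmax: 60.0
  pump_km_atp: 0.3
  pump_ph_floor: 4.8
  pump_backpressure_span: 2.4
  passive_h_permeability: 1900.0
  cl_channel_rate: 100.0
  ae2_density: 5.0
  ae2_turnover: 470.0
  ae2_km_hco3: 10.0
  ae2_km_cl: 10.0
  ae2_ph_gate_midpoint: 5.0
  ae2_ph_gate_steepness: 4.0
  co2_permeability: 50.0
  buffer_pka: 6.4
  buffer_forward_rate: 1.0e+6
cytosol:
  ph: 7.2
  atp_mM: 10.0
  cl_mM: 4.0
  hco3_mM: 12.0
  co2_mM: 1.9
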