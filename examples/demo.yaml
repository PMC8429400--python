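# End-to-end synthetic demo: reproduces the electrochemical worked example
# and exercises every pipeline stage deterministically.
seed: 7
outdir: out/demo
stages: [electro, calibration, cells, rates, simulate, lectin]
electro:
  ph_lumen: 6.0
  ph_cyto: 7.0
  k_lumen: 107.0
  k_cyto: 140.0
  cl_cyto: 4.0
cells:
  n_cells: 2000
rates:
  preset: null
simulate:
  preset: cos7_control
  bath: cl_hco3
  t_end: 25.0
lectin:
  alpha: 0.05
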