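# Reference parameter set: spherical receiver with surface receptors,
# pulsed point transmitter, Q=50 molecules per 10 ms pulse, 1/mu = 4 s.
label: table1_q50_mu4
geometry:
  Rr_um: 2.5        # receiver radius
  rs_nm: 4.0        # receptor radius
  n: 10000          # surface receptors
  d_um: 26.5        # TX-RX centre distance
medium:
  D_m2s: 1.18e-10   # ligand diffusion coefficient
emission:
  Q: 50
  delta_t_ms: 10.0
  t_end_s: 10.0
kinetics:
  trafficking_time_s: 4.0
numerics:
  dt_particle_ns: 100.0   # particle time step entering the bounce distance d*
  grid_dt_ms: 10.0
  integrator: trapezoid
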