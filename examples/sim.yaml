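# Desk-scale fluctuating-selection design: three periods, shifts at
# generations 50 and 100 after the (equilibrium-seeded) burn-in.
simulation:
  N: 1000
  L: 10000
  mu: 5.0e-6
  r: 2.3e-4        # region map length r*L = 2.3 crossovers per meiosis
  h: 0.5
  prop_selected: 0.05
  burn_in: 0
  init: equilibrium
  replicates: 5
periods:
  - {start: 0, end: 50, mean_s: 0.05}
  - {start: 50, end: 100, mean_s: -0.025}
  - {start: 100, end: 150, mean_s: 0.10}
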