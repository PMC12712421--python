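# Discrete before/after sampling straddling the generation-50 shift.
kind: discrete
shift_gen: 50
steps: 6
n_per_step: 40
spacing: 10
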