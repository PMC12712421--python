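# Museum/herbarium-style continuous sampling: 200 individuals over 150
# generations, density increasing toward the present.
kind: continuous
window: 150
total_n: 200
ramp: 1.01
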