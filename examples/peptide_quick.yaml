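# Desk-scale smoke configuration: short windows at 1 MHz for quick runs.
ph: 2.5
snr: 10.0
duration_per_aa: 0.002
sample_rate: 1.0e+6
side_chains: blocked
seed: 1
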