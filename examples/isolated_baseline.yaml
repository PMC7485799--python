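# Isolated amino-acid identification, baseline conditions:
# carboxyl group, pH 3.0, SNR 10, 100 ms per residue, free side chains.
ph: 3.0
snr: 10.0
chi: 0.2
distance_map: sqrt
duration_per_aa: 0.1
sample_rate: 1.0e+7
chunk_duration: 1.0e-3
filter_size: 3
side_chains: free
seed: 1
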