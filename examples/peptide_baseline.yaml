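# Peptide sequencing baseline: pH 2.5, SNR 10, shielding exp(-0.2 sqrt(d)),
# 100 ms per residue, blocked side chains, tryptic N-terminal peptides <= 50.
ph: 2.5
snr: 10.0
chi: 0.2
distance_map: sqrt
duration_per_aa: 0.1
sample_rate: 1.0e+7
chunk_duration: 1.0e-3
filter_size: 3
side_chains: blocked
enzyme: trypsin
max_peptide_length: 50
replicates: 1
seed: 1
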