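# protonseq

A feasibility simulator for **protonation-based single-molecule protein
sequencing**: identifying amino acids by watching the terminal carboxyl group
of a surface-anchored peptide stochastically bind and release protons.

## The idea

A protonatable group in solution is a two-state system: protonated (*on*,
-COOH) or deprotonated (*off*, -COO⁻). Transition rates follow from the
solution pH and the group's pKa:

```
k_on  = 10^6 Hz                      (reprotonation; expected off-time 1 µs)
k_off = 10^(6 + pH − pKa) Hz         (deprotonation)
```

so dwell times are exponential and the stationary protonated fraction is the
Henderson–Hasselbalch form `p = k_on/(k_on + k_off) = 1/(1 + 10^(pH − pKa))`.
At `pH = pKa` the group is protonated exactly half the time. Because every
amino acid has its own carboxyl pKa, the *average on-fraction* of a long
charge-signal recording identifies the residue — and Edman-style removal of
one terminal residue per measurement window turns that into sequencing.

The simulator renders this telegraph signal realistically:

- **Shielding** — a protonation event at residue distance *d* from the anchor
  is attenuated by `exp(−χ·√d)` (χ = 0.2 by default), so signals weaken along
  the peptide;
- **Side chains** — C, D, E, H, K, R and Y carry their own protonatable
  groups whose telegraph signals superpose on the terminal signal (they can
  be simulated `free` or chemically `blocked`);
- **Amplitude jitter** — each dwell event's amplitude is drawn from
  `S·N(exp(−χ√d), σ²)` with σ = 0.1, modelling slow peptide motion;
- **1/f noise** — Voss–McCartney pink noise, normalised to unit RMS; the
  initial SNR *S* is the anchor-point on-amplitude in noise-RMS units;
- **Finite sampling** — traces are sampled at 10 MHz; dwell events shorter
  than the sampling interval can be missed.

Traces are reduced to the summary statistic used throughout: 1 ms chunks,
size-3 median filter, threshold at the midpoint of the filtered extrema, and
the **median chunk on-fraction** per residue window. Identification is by
nearest calibrated on-fraction (single residues) or least-squares matching of
the per-position on-fraction profile against same-length peptides from a
digested reference database (peptides). Protein identification uses unique
N-terminal tryptic peptides; the package reports the peptidome recovery rate
(PeRR), proteome recovery rate (PRR) and unique PRR (PRR restricted to
proteins with a unique N-terminal peptide).

## Worked example

Generate a small synthetic protein database, sequence one peptide, and run
the full recovery experiment (the quick config uses 2 ms windows at 1 MHz):

```sh
$ protonseq make-proteome --n 5 --seed 1 --out demo.fasta
wrote 5 proteins to demo.fasta

$ protonseq simulate-peptide FWHK --config examples/peptide_quick.yaml
position	residue	median_on_fraction	n_chunks
4	K	0.284500	2
3	H	0.069500	2
2	W	0.375000	2
1	F	0.558500	2

$ protonseq evaluate demo.fasta --config examples/peptide_quick.yaml
PeRR	1.0000
PRR	1.0000
unique_PRR	1.0000
length	total	correct
3	1	1
4	1	1
5	1	1
13	1	1
45	1	1
```

The `simulate-peptide` rows are read C-terminus first: the initial window
measures K at distance 4 from the anchor, the last window measures F adjacent
to the anchor. F (pKa 2.58, above the pH of 2.5) stays protonated more than
half the time (0.56); H (pKa 1.77) is mostly deprotonated and its short
on-events are additionally thinned by the finite sampling rate, giving 0.07.
All five N-terminal tryptic peptides of the toy database are unique and
correctly re-identified, so all three recovery rates are 1.

The same machinery is available as a library (`protonseq.run_isolated_experiment`,
`protonseq.run_peptide_experiment`, …); see `docs/methods.md` for the model
details and parameter defaults.

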