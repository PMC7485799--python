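# Methods

## Model

Each protonatable site — the free terminal carboxyl group of an anchored
peptide, and optionally the side-chain groups of C, D, E, H, K, R, Y — is an
independent continuous-time two-state process. The off→on (reprotonation)
rate is fixed at `k_on = 10^6 Hz`; the on→off rate is
`k_off = k_on · 10^(pH − pKa)`. Dwell times are exponential:
on-times ~ Exp(k_off), off-times ~ Exp(k_on). The stationary protonated
fraction is `1/(1 + 10^(pH − pKa))`. The absolute value of `k_on` only sets
the time scale: rescaling it together with the sampling rate and measurement
time leaves every result unchanged.

The pKa table (20 residues; carboxyl, amine and — for the seven titratable
residues — side-chain values) ships as a TSV inside the package and can be
overridden, since published pKa tables differ and in reality pKa values are
site-specific. Only carboxyl-group sequencing is modelled: side-chain pKa
values lie well above the terminal carboxyl pKa range, so working at acidic
pH minimises their interference; the amine-group variant is out of scope.

A measurement window of duration *T* for the residue at distance *d* from the
anchor renders:

1. the terminal carboxyl telegraph signal, with per-event amplitude
   `S · N(exp(−χ·f(d)), σ²)`, `f(d) = √d` (worm-like-chain distance proxy),
   σ = 0.1, off-level 0;
2. one such signal per free side chain still attached (distance = that
   residue's index from the anchor, same shielding law);
3. unit-RMS pink noise (Voss–McCartney: 16 staggered white sources, source
   *k* held over 2^k samples, linearly rescaled to empirical RMS 1). The
   initial SNR *S* is therefore the anchor-point on-amplitude in noise-RMS
   units.

Rasterisation at rate *r* (default 10 MHz) assigns each sample instant the
amplitude of the covering event (ties at a boundary go to the newer event),
so events shorter than a sample interval can vanish — a deliberate physical
feature of the model, not an artefact.

## Extraction

A trace is cut into non-overlapping 1 ms chunks (trailing partial chunk
dropped so chunk statistics are i.i.d.). Each chunk is median-filtered
(size 3; edges shrink the window, so a 2-element median is the midpoint),
thresholded at `(max + min)/2` of the filtered chunk, and the fraction of
filtered samples strictly above the threshold is the chunk on-fraction. A
constant chunk yields 0 by this convention; the classifier is calibrated with
the same convention, so any consistent choice works. The per-window summary
is the median over chunk on-fractions (even counts: midpoint of the central
pair). The statistic is invariant under positive affine transforms of the
signal, which makes it insensitive to the absolute amplitude scale — and
hence to shielding, until the signal sinks into the noise.

## Calibration and identification

Identification needs a table of expected median on-fractions per residue.
Two methods are provided:

- **analytic** — the closed-form stationary fraction of the carboxyl group.
  Exact only in the limit of infinitely fast sampling with silenced side
  chains: at 10 MHz the mean on-time at pH 3 is 0.06–0.38 µs (at most ~4
  sample intervals), the median filter removes a large share of on-events,
  and measured fractions sit 0.01–0.035 below the analytic values (e.g. T
  measures ≈0.082 against an analytic 0.110). A nearest-value classifier
  with this table misassigns systematically (T→P, W→A).
- **empirical** (default for experiments) — every residue is pushed through
  the *full* measurement chain (superposition, the run's noise model,
  rasterisation, extraction) for one long window (1 s default) under a fixed
  calibration seed, and the median chunk on-fraction is tabulated. This is
  the package's design choice where the procedure was genuinely open: an
  expected-value table is only useful to a minimum-distance classifier if it
  matches the distribution of the measurements it will classify. The choice
  matters most for free side chains: the chunk threshold of a superposed
  multi-level signal sits on different levels with and without noise, so a
  noise-free calibration of, say, H at pH 3 (≈0.03) is biased by ≈0.3
  against noisy measurements (≈0.5 once side-chain off-dips pull the chunk
  minima down).

Isolated residues are classified to the nearest calibrated value (ties:
alphabetical). Peptides are matched against all same-length peptides of the
digested reference by minimising the summed squared deviation between
observed and calibrated per-position on-fractions — the maximum-likelihood
rule under i.i.d. Gaussian errors with equal variances (ties: lexicographic).
Position-dependent variance weighting (later windows are measured nearer the
anchor and are cleaner) is deliberately not applied.

Confusion matrices order residues by ascending calibrated on-fraction (the
operational proxy for expected on-time, side chains included). The
confusability partition is found by dynamic programming over partitions
contiguous in that order, maximising the number of groups subject to every
residue having ≥95% identification mass inside its own group; the
all-residues group is always feasible, and among maximal partitions the one
with the shortest trailing groups is returned, making the search
deterministic.

## Proteome handling

Digestion cleaves after K/R (trypsin), E (Glu-C) or M (CNBr); the
no-cleavage-before-proline refinement of trypsin is not applied (the plain
rule is used throughout). Peptides above a length cutoff (50 by default) are
discarded. Protein identification uses the first digestion product
(N-terminal peptide, initiator methionine retained); proteins whose
N-terminal peptide is shared — or exceeds the cutoff — can never be
identified and count as failures in PRR. FASTA records containing
noncanonical residues (U, X, B, Z) are skipped with a warning and excluded
from all denominators.

The synthetic proteome generator stands in for a real database so the whole
pipeline is testable offline: i.i.d. sequences with uniform residue
composition and log-normal lengths (median 350, log-sd 0.5 — a realistic
protein-length spread; composition and distribution are configurable,
deterministic under seed). It deliberately lacks the homology structure,
shared N-terminal isoforms and biased composition of a real proteome, so
recovery rates measured on it say nothing quantitative about real databases —
they exercise correctness (enumerable noise-free recovery) and direction
(monotone trends in SNR, measurement time, shielding and side-chain mode).

## Numerical and reproducibility choices

- Dwell sampling truncates the final event at the window boundary
  (discarding it would bias short windows); the initial state is stationary
  Bernoulli so on-fraction estimates are unbiased from time zero.
- Traces accumulate in float32 (signal levels are O(10), noise RMS 1;
  float32 rounding is far below the extraction's decision scales).
- Seeding is counter-based: a master seed plus a (task, replicate, position)
  spawn key per simulation, so any replicate's draws are independent of how
  many replicates are requested. Calibration uses its own fixed seed and is
  cached per condition.
- Traces are generated in one block; windows beyond ~10^7 samples (1 s at
  10 MHz) are the practical ceiling, and no chunked-generation mode exists.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| pH | 2.5 peptides / 3.0 isolated | sets every k_off via pH − pKa |
| SNR *S* | 10 | anchor on-amplitude over noise RMS |
| χ | 0.2 | shielding exponent in exp(−χ√d) |
| *T* per residue | 100 ms | window length; estimator SD ∝ 1/√T |
| sample rate | 10 MHz | below ~3/k_off, on-events are thinned |
| chunk / filter | 1 ms / 3 | extraction granularity and outlier removal |
| side chains | blocked (peptides) | free mode superposes side-chain signals |
| calibration window | 1 s | empirical-table precision |

## Known limitations

- The empirical calibration makes classification self-consistent with this
  pipeline; published accuracy figures for the same physical setup depend
  sharply on the (often under-specified) extraction and expected-value
  conventions, so cross-implementation accuracy comparisons at identical
  nominal conditions can differ by tens of percentage points even when both
  implement the same kinetics. Within this package, all accuracies are
  reproducible and the monotone dependencies on SNR, measurement time, pH
  asymmetry and shielding hold.
- A and G share a carboxyl pKa and are inherently indistinguishable in
  isolation; near-degenerate pairs (Q/K, I/L, V/M) separate only with long
  windows.
- Thermal and shot noise, device transfer functions, site-specific pKa
  shifts, peptidase (random-time) cleavage and de novo sequencing are out of
  scope.
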