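# Methods

## Problem and model

The package classifies fixed-length multichannel EEG windows as pre-ictal
(1 h to 5 min before an annotated seizure onset) or inter-ictal (far from
any seizure). The model factors the problem into three stages, mirroring
the three kinds of structure that distinguish the classes:

1. **Frequency**: a depth-4 wavelet packet decomposition tiles 0..fs/2 into
   16 equal sub-bands per channel; each band is summarized by the energy of
   its terminal coefficients. Unlike the plain wavelet transform, the packet
   tree splits the detail branch too, so high-frequency structure — which
   increases before seizures — is resolved as finely as low-frequency
   structure.
2. **Space**: channels become nodes of a weighted graph whose edges are
   absolute Pearson correlations between per-channel band-energy vectors;
   a two-layer Chebyshev spectral graph convolution encodes each window
   into an 18-value status code (one value per channel).
3. **Time**: a GRU consumes consecutive status codes in chronological order
   and an MLP head emits class probabilities.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| window length | 5 | s | long enough for a depth-4 decomposition at 256 Hz (1280 samples, 80 coefficients per terminal node); standard in this literature |
| pre-ictal span | 3600 → 300 | s before onset | the labeling rule; accumulating abnormality appears within the hour before onset, and the last minutes are excluded as transition |
| inter-ictal guard | 14 400 | s | distance from any seizure for the negative class; the boundary is graphical in most dataset descriptions, so it is a configurable knob |
| pre-ictal overlap | 0.5 | — | doubles positive-window density to balance classes |
| wavelet | db4 | — | smooth orthogonal Daubechies family; order configurable (see leakage note) |
| Chebyshev order K | 3 | — | captures 2-hop neighborhoods on an 18-node graph |
| encoder widths | 16 → 32 → 32 → 18 | — | small enough to train stably on hundreds of windows |
| sequence length | 5 | windows | one prediction per 5 consecutive windows (25 s at defaults), label taken from the constituent windows (single-label runs) |
| GRU hidden / MLP hidden | 32 / 16 | — | matched to the 18-value input |
| learning rate | 0.01 | — | Adam initial rate |
| λ (L2) | 5·10⁻⁴ | — | weight decay on weight matrices only, biases exempt |
| epochs / batch | 50 / 32 | — | sufficient for convergence on the synthetic task |

## Design choices where the design was open

- **Node features.** The encoder consumes *relative* band energies (each
  channel row sums to 1) rather than raw energies: raw band energies are
  scale-dependent (µV²·samples) and condition gradient training poorly,
  while relative energies are scale-free. Raw energies remain available
  (`use_relative=False`). Pearson edge weights are identical either way,
  since correlation is invariant to positive per-row scaling.
- **Correlation input.** Edges default to correlations between band-energy
  vectors (correlation-of-features); correlating raw time series is offered
  as `mode="raw_signals"` since both readings are defensible.
- **Edge sign.** Adjacency uses |r| — the normalized-Laplacian machinery
  requires nonnegative weights — and signed correlations are retained
  separately.
- **Terminal-node order.** The natural packet-tree order interleaves
  frequencies; nodes are re-sorted to ascending frequency order so band k
  always means the k-th frequency slab.
- **Boundary handling.** Signals are extended by periodization, which keeps
  the transform exactly orthonormal: total band energy equals signal energy
  to ~1e-15 relative (the test suite enforces 1e-8).
- **Laplacian.** Symmetric normalized form; isolated nodes get zero rows
  and λ_max is floor-clamped to 1e-6, so an edgeless graph yields L̃ = −I
  rather than a division by zero. λ_max is computed by dense
  eigendecomposition — exact and cheap at 18×18.
- **GRU formulation.** The candidate state applies the reset gate
  elementwise to the recurrent term, C̃ = tanh(W s + R ⊙ (U C)), the
  standard reading; gates are bias-free, matching the defining equations.
- **MLP head.** One hidden ReLU layer (width 16) — the minimal reading of
  "multilayer" — then softmax over two classes.
- **Split protocol.** Within every (source, label) group the leading 70 %
  of segments train and the trailing 30 % are held out; sequences are built
  within each side only, so no overlapping window ever straddles the split.
  Note that with 50 %-overlap pre-ictal windows, adjacent windows *within*
  a side still share samples — that is the class-balancing device, not
  leakage across the evaluation boundary.
- **FPR and F1 scales.** FPR and F1 are reported as ratios (0.0106-style),
  the other five indicators as percentages; undefined metrics
  (zero denominators) are reported as missing, never as 0.

## Synthetic data: what it emulates and what it does not

The generator plants exactly the two contrasts the pipeline is built to
detect:

- **Spectral profile**: each class has a target relative-energy profile
  over the 16 sub-bands, realized as sinusoids at sub-band center
  frequencies with amplitude ∝ √weight. Defaults: inter-ictal dominated by
  low-frequency bands {1,3,5}, pre-ictal by high-frequency bands
  {10,12,14} (84 % of energy on the dominant set, the rest spread evenly),
  mirroring the increase of high-frequency content before seizures.
  Dominant bands are deliberately *non-adjacent*: tones in adjacent bands
  exchange up to ~9 % of their energy through filter-overlap cross-terms at
  packet-tree boundaries, which would scramble the planted profile.
- **Coupling**: every channel mixes a shared source (weight √c) with an
  independent per-channel source (weight √(1−c)), so the expected pairwise
  Pearson correlation equals c. Defaults: c = 0.9 pre-ictal vs 0.1
  inter-ictal.

White noise (default 10 µV SD against a 50 µV-RMS oscillatory part) is
added on top. Streams derive from `SeedSequence([seed, counter, label])`
(PCG64), so datasets are bit-reproducible; `make_dataset` gives segment i
of class c the child seed `seed·2²⁰ + 2i + c`.

Deliberately **not** modeled: 1/f background spectra, spikes and artifacts,
ictal waveforms, non-stationarity within a window, volume-conduction
structure, patient heterogeneity. Consequently, a perfect score on the
synthetic task shows that the pipeline recovers planted spectral/spatial
contrast end to end — it says nothing about performance on real EEG, where
the contrast is weaker, noisier, and drifts over time.

### Wavelet leakage and the generator audit

Depth-4 Daubechies packet filters leak substantially between neighboring
bands: a band-center tone keeps only 60–99 % of its energy in its own band
under db4 (78 % worst-case even at db30), though the *ranking* is always
correct (the tone's band is the argmax for all 16 bands). Tests that audit
what the generator planted therefore measure energies with the discrete
Meyer wavelet (`dmey` — orthogonal and frequency-sharp: ≥ 95 % self-band
share everywhere except the two mid-spectrum bands at 79 %), where planted
profiles are recovered within 5 % absolute per band (≤ 1.5 % when averaged
over channels and segments). The pipeline default remains db4; for the
classification task only the between-class contrast matters, which survives
leakage untouched.

## Numerical notes

- All learnable computation is numpy float64 with analytic gradients; a
  central-finite-difference test pins every parameter tensor's gradient to
  < 1e-5 relative error. Single-threaded numpy makes training bit-
  deterministic for a fixed seed (parameter init and batch shuffling use
  independent seeded streams).
- The Chebyshev operators T_k(L̃) depend only on each window's graph, never
  on learnable parameters, so they are precomputed per window; both
  convolution layers then reduce to tensor contractions, and the backward
  pass reuses the operators via their symmetry.
- Softmax is computed with max-subtraction; cross entropy floors
  probabilities at 1e-12; sigmoid is evaluated in its numerically stable
  branch form.
- Degenerate inputs have fixed policies: constant signals correlate as 0
  (with a warning), all-zero windows yield zero relative energies with a
  flag, intervals shorter than one window yield empty segment lists, and a
  pre-ictal interval emptied by the recording start or a prior seizure is
  skipped with a warning.

## Problem sizes used in the shipped experiments

The acceptance experiment uses 200 generated segments per class
(5 s × 18 channels), a 70/30 blocked split, sequences of 5 windows, and 50
training epochs — about half a minute on one CPU. These sizes were chosen
as the smallest round numbers at which the held-out evaluation has a few
hundred sequences and training fully converges; results are stable across
seeds.

## Known limitations

- Real-data evaluation (e.g., CHB-MIT) requires the external download and
  a per-patient protocol (splits, epochs, alarm post-processing) that this
  package does not fix; the I/O path is exercised against EDF files written
  by the package's own writer.
- The EDF writer is minimal (16-bit, 1-s records, integer sampling rates,
  whole-second durations) — sufficient for round-tripping synthetic
  recordings, not a general-purpose exporter.
- No artifact rejection, filtering, re-referencing or resampling; inputs
  are assumed clean and single-rate.
- One GRU layer, no attention, no alarm logic (refractory periods,
  firing-power smoothing); sequence label assumes single-label runs.
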