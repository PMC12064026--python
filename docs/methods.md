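# Methods

This note documents the models, conventions and numerical choices behind
`reefscape`, in the order data flows through the pipeline.

## Audio front end

All analysis runs at 16 kHz (recordings are resampled with a polyphase
filter), capping the usable spectrum at 8 kHz — the upper edge of the
snapping-shrimp band. Minutes are split into non-overlapping 0.96-s
segments; a 60-s minute gives exactly 62, with any trailing remainder
(< 0.96 s) discarded.

The short-time Fourier transform uses 25-ms Hann windows every 10 ms with no
padding, so frame count = ⌊(n − window)/hop⌋ + 1 and every frame covers real
signal. Log-mel patches are built from a *single* STFT over the whole minute,
mel-integrated into 64 triangular filters (mel = 2595·log₁₀(1 + f/700),
spanning 125–7500 Hz, unnormalised weights), log-transformed with an
additive offset of 0.01, and partitioned into non-overlapping 96-frame
patches. Computing one STFT per minute and partitioning frames — rather than
an STFT per 0.96-s chunk — is what makes a 0.96-s window correspond to
exactly 96 frames; a per-segment STFT would yield 94. Both routes agree that
a 60-s minute produces 62 windows.

Band slicing keeps spectrogram bins whose center frequency lies in the
half-open interval [f_low, f_high). Everything below 50 Hz is excluded from
analysis bands to suppress geophony and recorder self-noise.

## Acoustic indices and the compound index

Per segment, seven indices are computed on each of three bands — low
(50–2000 Hz), medium (2000–8000 Hz), full (50–8000 Hz) — plus NDSI, for 22
values. Conventions that the index definitions leave open:

- **Spectral vs envelope domain.** ACI, ADI/AEI, Hf and BI operate on the
  band-sliced magnitude spectrogram; Ht and M operate on the fast amplitude
  envelope (max |x| per 256-sample block) of the *band-passed waveform*
  (zero-phase FFT masking), so that every band's temporal statistics are
  band-limited too. H is the product Ht·Hf.
- **dB reference.** ADI/AEI occupancy and BI use decibels relative to the
  spectrogram's own maximum (20·log₁₀(S/S_max)) — consistent with treating
  recordings as uncalibrated; no index depends on absolute level except M,
  which scales linearly with amplitude.
- **ADI/AEI sub-bands.** Ten equal-width frequency sub-bands spanning the
  sliced band (bin step = range/10); occupancy is the fraction of
  spectrogram cells above −50 dB. ADI is the natural-log Shannon entropy of
  the normalised occupancies; AEI is their Gini coefficient,
  Σᵢⱼ|xᵢ−xⱼ|/(2n²μ). Because ADI and AEI strongly covary, only one fills
  the diversity slot of the compound index; the default is AEI, switchable
  in `IndexConfig`.
- **NDSI bands.** Default anthrophony 50–2000 Hz versus biophony
  2000–8000 Hz; a `"williams2022"` preset provides the alternative
  (50–1000 / 2000–5000 Hz) convention. Power is the sum of squared
  magnitudes over band bins.
- **Degenerate inputs.** Silent segments produce defined neutral values
  (entropies 0, NDSI 0, occupancy indices 0) with a structured
  `IndexWarning` instead of an exception, so batch runs survive dropout
  minutes.

The per-minute compound index is the mean and *population* standard
deviation (divisor n) of each of the 22 features across the minute's
segments — 44 named values (`mean_ACI_low`, `sd_ACI_low`, …, `sd_NDSI`) in a
fixed order.

## Embedding contract

Extractors are sklearn-style transformers mapping clips to (n, d) matrices,
looked up in a registry so externally trained networks plug in unchanged.
The built-in `logmel_projection` extractor applies a fixed, seeded Gaussian
random projection (entries ~ N(0, 1/6144)) to each flattened 96×64 patch
and averages the 62 patch vectors per minute. It is a *weightless stand-in*
with the same input pre-processing, output dimension (128) and per-minute
averaging as a pretrained convolutional embedding network; as a random
projection it approximately preserves relative distances
(Johnson–Lindenstrauss), which is the property the downstream clustering
consumes. It is not a learned feature extractor and carries no semantic
audio knowledge.

## Unsupervised evaluation

Embeddings are column-standardised before dimensionality reduction: the
compound index mixes scales spanning orders of magnitude (BI in dB·Hz,
entropies in [0, 1]), and unscaled distances would be dominated by a few
columns. Reduction to 10 dimensions uses UMAP (seeded); a deterministic
in-package PCA (eigendecomposition with a fixed sign convention: the
largest-magnitude loading of each component is positive) is available where
bitwise platform-independence matters.

Affinity propagation is implemented directly (Frey–Dueck responsibility/
availability updates). Similarity is the negative squared Euclidean
distance; the exemplar preference defaults to the median off-diagonal
similarity; damping 0.5, max 200 iterations, convergence declared when the
exemplar set is stable for 15 iterations. After convergence each cluster's
exemplar is refined to the member maximising intra-cluster similarity and
labels are re-derived — matching the conventions of the widely used
reference implementation, which the test suite verifies exemplar-for-
exemplar on toy problems. If no exemplar emerges (e.g. all-identical
points), a single best-effort cluster is returned with `converged=False`.

Cluster fidelity is the Pearson χ² (no continuity correction) of the
cluster-by-class contingency table after dropping empty rows/columns; a
table degenerate to one row or column scores 0 with 0 degrees of freedom.
Significance of the alignment is assessed against a label-permutation null
(cluster assignments fixed, class labels permuted).

## Blocked supervised evaluation

Splits are built at the block level — whole sites, or site–date
combinations — with 66–75 % of minutes in training and held-out blocks
divided evenly between validation and test (odd block to test). All valid
assignments are enumerated (for ≤ 18 blocks) and a requested number sampled
without replacement; if fewer exist, all are returned. Every emitted plan is
asserted leakage-free, not assumed.

Per plan, `n_models` classifier instances (default 50 random forests with
library-default parameters) are trained with consecutive seeds; the instance
with the highest validation accuracy — ties to the lowest seed — is scored
on the test block. Frame-level classifiers are scored per minute by majority
vote with ties broken toward the smallest label. Records carry flags (e.g.
single-class partitions) rather than being silently dropped. Cross-method
comparison uses one-way ANOVA and, when significant at α = 0.05, all-pairs
Tukey HSD with compact-letter grouping (A = highest-accuracy group).

A property of this protocol worth knowing: with few held-out blocks, the
null (no class signal) does **not** center test accuracy on 1/K. Removing a
block skews the training class balance, and selecting the best-on-validation
model against a (often single-class) validation block anti-correlates test
predictions with the test block's class; observed null accuracies sit
noticeably *below* 0.5 for two balanced classes. The meaningful null check
is therefore one-sided — no spurious *skill* above the binomial band — and
that is what the tests assert.

## Synthetic soundscape generator

The generator renders the structure the pipeline needs to be tested against,
not an acoustically faithful reef:

- **Snaps**: Poisson-timed (rate × duration events) 1-ms transients, each an
  exponentially damped sinusoid (decay 0.15 ms, 0.03-ms attack ramp) at a
  random carrier within 2.8–7 kHz and peak amplitude uniform in [0.5, 1].
  The damped-sinusoid shape gives each snap a clean unimodal Hilbert
  envelope, so rendered event counts can be validated by envelope peak
  detection — a band-passed noise burst, the other natural choice, rings
  under a brick-wall filter and defeats counting. Energy is concentrated in
  the 2–8 kHz band (≈ 90 % at 16 kHz rendering).
- **Fish chorus**: Poisson-timed calls of 3–5 Hann-windowed 80-ms tone
  pulses at fundamentals restricted to 50–1000 Hz, repeated every ~120 ms;
  > 90 % of power falls in the 0.05–1 kHz band for mid-band tone sets.
- **Ambient floor**: Gaussian noise shaped to power ∝ f^−slope (default
  slope 1) and scaled to a target RMS.
- **Coloration**: site and recorder responses are gentle seeded ±3 dB
  piecewise-linear dB tilts applied in the FFT domain, emulating site
  fingerprints and instrument bias; recorders rotate between sites by day
  (round-robin by default).
- **Diel profile**: biological rates are multiplied by
  1.25 + 0.75·cos(2π(h−6)/12) — a two-peak crepuscular curve in [0.5, 2]
  peaking at 06:00 and 18:00. Minutes are scheduled over the diel cycle with
  a golden-ratio stride, giving low-discrepancy hour coverage for any minute
  count and avoiding aliasing against the 12-h period of the profile (a
  uniform grid can land every minute on the same phase).
- **Determinism**: every component draws from its own child stream of the
  scene seed, so scenes regenerate byte-identically and component layers mix
  linearly before peak normalisation.

Amplitudes are dimensionless throughout; no propagation, calibration, lunar
or weather effects are modelled. What passing tests show is that the
*pipeline* recovers class structure that is present and reports none when it
is absent — not that any particular real reef would behave like the
generator.

### Study conditions used by the tests and acceptance script

- Clustering fidelity: 2 classes × 4 sites × 10 minutes (40 minutes), with
  strongly divergent classes (snap rate 60 vs 10 s⁻¹, chorus rate 4 vs
  1 s⁻¹): χ² on true classes must exceed the 99th percentile of 200 label
  permutations for both embedding types.
- Supervised recovery: 12 sites × 5 minutes, 10 plans × 50 models with
  10-tree forests. Strong divergence must yield mean test accuracy ≥ 0.9;
  identical class generators must stay at or below the upper edge of the
  99 % binomial band around 0.5 (one-sided, per the selection-bias note
  above).
- Single-index benchmark: 8 sites × 4 minutes with mild divergence (snap
  rate 30 vs 20 s⁻¹), where class ranges genuinely overlap and the
  unambiguous fraction sits strictly below blocked-classifier accuracy.

These sizes keep the full suite within a few minutes on one CPU while
leaving each statistical check comfortable margins; they were chosen as the
package's standard desk-scale conditions.

## Known limitations

- The 128-d projection embedding shares only the interface of a pretrained
  network; comparisons between it and the compound index say nothing about
  how a trained CNN would rank.
- UMAP reduction is reproducible per seed but not identical across library
  versions; the PCA fallback is fully deterministic.
- The Mann–Whitney p value uses the exact distribution only for tie-free
  samples with n·m ≤ 400, otherwise the tie-corrected normal approximation
  with continuity correction.
- The range-overlap definition of "unambiguously classifiable" is the
  strictest natural choice (any overlap disqualifies the overlapped span);
  quartile-based definitions would report higher fractions.
- Affinity propagation is O(n²) memory and O(n²·iterations) time; for the
  dataset sizes here (≤ a few thousand minutes) that is negligible.
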