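# Methods

This note records the model, the defaults and the design decisions behind
`breathcam`, and what the synthetic test bed does and does not establish.

## Signal model and assumptions

A fixed camera observes a breathing subject against a mostly static
background. Respiratory chest motion displaces intensity edges, so a
breathing pixel's value is modelled as

    value_c(t) = baseline_c + gain · phase · ref(t) + ε_c(t),

with `phase ∈ {+1, −1}` (the two flanks of a moving edge), `ref(t)` the
breathing waveform, and ε i.i.d. Gaussian sensor noise. The method
assumes: (1) the subject stays in frame and does not translate grossly —
gross motion breaks per-pixel stationarity; (2) breathing rate lies in
10–40 bpm, which fixes the minimum window length (two periods of the
slowest breath → ≥ 12 s) and the 5 fps processing rate (Nyquist 2.5 Hz ≫
0.667 Hz); (3) both in-phase and antiphase pixel populations exist, which
holds whenever a moving edge is visible.

## Pipeline parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| spatial factor | 8 (nominal capture) | — | block mean over 8×8 suppresses noise and cuts compute; 640×480 → 80×60 |
| processing rate | 5 | fps | covers the breathing band with ×4 margin |
| window length | 12 | s | two periods at 10 bpm |
| hop | 1 | s | dense bpm updates; the method only requires overlap |
| labeling threshold T | 0.7 | — | correlation magnitude above which a pixel is a respiration pixel |
| detector widths | 16/32/64/128 | channels | reaches the fixed 128-wide embedding in four stride-2 blocks; ~111k parameters, a deliberately lightweight model |
| classifier threshold | 0.5 | probability | unbiased sigmoid cut |
| clusters k | 6 | — | enough clusters to sequester noise groups; the mutual-inclusion argmax then picks the symmetric pair (typical symmetric point clouds show 4–6 natural groups) |
| peak min distance | 60/45 ≈ 1.33 | s | just under the 1.5 s period at 40 bpm |
| peak prominence | 0.3 × signal SD | — | rejects ripple without suppressing shallow breaths |
| training | Adam, lr 1e-3, batch 256, 15 epochs, 10% validation | — | standard defaults; all seeded |
| augmentation | scale U[0.5, 2], shift U[−20, 20] (8-bit), inversion p = 0.5, per channel | — | spans plausible clothing/background contrast; inversion is label-preserving because labels use \|r\| |

Temporal resampling averages each group of source/target consecutive
frames (anti-aliasing); plain decimation is available as an option. The
per-pixel scalar trajectory used for labeling and fusion is the channel
mean of the mean-centered RGB trace — achromatic motion edges move all
channels together, so averaging raises SNR; a max-|r|-per-channel option
exists for strongly chromatic scenes.

## Network

Input is one pixel's z-scored `(l, 3)` window. Each residual block is
conv(k=3, stride 2) → BN → ReLU → conv(k=3) → BN, summed with a projected
(1×1, stride 2, BN) shortcut, then ReLU. Global average pooling over the
remaining time steps yields the 128-dimensional embedding; a fully
connected layer with batch normalization and a sigmoid produces the
respiration probability, trained with binary cross-entropy. For l = 60
(12 s at 5 fps) the temporal lengths are 30, 15, 8, 4; a configuration
whose stride-2 stack would shrink the sequence below 2 steps is rejected
with the maximum depth for that input length. The implementation is
self-contained NumPy (im2col convolutions, explicit backpropagation,
Adam); every layer's gradient is verified against central finite
differences in the test suite, and inference is bit-stable for fixed
weights.

## Estimator details

Mirrored copies participate in clustering and pair selection only; fusion
averages original signals, so no pixel is double-counted. Mutual
inclusion is only evaluated for distinct clusters: a cluster "symmetric
with itself" would have to contain antipodal points, i.e. near-zero
signals, and carries no usable phase split. Ties in the argmax break
deterministically — clusters ranked by descending size (then index), and
the lexicographically first maximising pair in that ranking wins; larger
clusters represent more pixels and hence more evidence. Zero-variance
(constant) pixel traces are dropped before clustering, because cosine
distance is undefined for them.

The fused trace's sign is physically ambiguous (the camera cannot tell
inhale from exhale), so the output is canonically oriented: first local
maximum before first local minimum. Evaluation additionally sign-aligns
the stitched trace with the reference before correlating. The continuous
trace is assembled from overlapping window traces by unit-scaling each,
flipping it when it anti-correlates with the already-accumulated overlap,
and averaging.

## Vitals and agreement statistics

Breath peaks come from `scipy.signal.find_peaks` with the distance and
prominence defaults above, refined to sub-sample positions by parabolic
interpolation through each peak triplet (at 5 fps integer peaks quantise
the PPI in 200 ms steps; refinement removes most of that). bpm is
60000 / mean PPI(ms) over the window — computed from intervals, not from
peak counts. Windows with fewer than two detectable peaks report a
missing bpm (the apnea case), never a number. The reference trace runs
through the identical windowing and peak pipeline, so both sides share
one definition of bpm. Bland–Altman differences are estimated − reference;
LOA uses the sample standard deviation (ddof = 1), the standard
Bland–Altman convention. R² comes from an ordinary least-squares fit of
estimated on reference bpm and is undefined (NaN/null) when the reference
rate does not vary.

## Synthetic scene generator

The generator is the package's test bed and stands in for subject
recordings, which cannot be redistributed for privacy reasons. Scenes
default to 64×48 px at 10 fps, processed at spatial factor 4 to a 16×12
grid at 5 fps — the same pipeline semantics as the nominal 640×480 at
20 fps capture (factor 8) at roughly 1/25 the cost; the preprocessing
contract at the nominal geometry is covered by its own tests. Defaults:
two 16×24 px breathing regions (one in-phase, one antiphase), modulation
gain 10 and noise SD 2 on the 8-bit scale, with SD 4 used as the
"moderate noise" test condition. Modulation depth of real clothing is not
documented anywhere we can calibrate against, so the gain is a
convention chosen to put per-pixel SNR in a regime where labeling is
clean but single-pixel traces are visibly noisy. The breathing waveform
integrates instantaneous frequency, so rate steps never produce waveform
discontinuities; apnea freezes the phase (constant value). A skewed
fast-exhale waveform is available because real belt traces are not
sinusoidal and peak detection should not be tested on pure tones only.
The guideline patterns mirror a training protocol of staircase
(10→40 bpm by 5 every 20 s), rapid alternation (up to 30 bpm every 20 s),
and rate steps of 10 interleaved with 10 s apnea pauses; the apnea
guideline is stated ambiguously in prose, and this package fixes it as
breathe 10 s / pause 10 s, twice per rate.

The Experiment-2 analogue adds a 12×12 px textured block oscillating
horizontally (amplitude 8 px) at 1.3 Hz — periodic, non-respiratory
(above the 0.667 Hz band edge, below the 2.5 Hz processing Nyquist), and
spatially disjoint from the breathing regions by construction.

What the generator does **not** emulate: gross subject motion,
illumination changes and shadows, camera compression artifacts, chromatic
motion edges, and breathing-correlated secondary motion (e.g. shoulder
sway). Passing tests therefore demonstrate the pipeline's correctness and
its noise/distractor behaviour under the stated signal model — not
performance on arbitrary real-world footage.

## Numerical choices and degenerate inputs

- Pearson correlation returns 0 (with a log note) for zero-variance
  inputs — static pixels and apnea windows are "uncorrelated", which
  makes apnea-only windows label 0 and report missing bpm end to end.
- The labeling threshold comparison is inclusive (|r| = T → label 1).
- z-scoring maps zero-variance channels to all-zeros rather than NaN.
- Block-mean downsampling handles ragged edges by averaging the pixels
  actually present (output size ceil(dim/factor)).
- Temporal resampling requires an integer fps ratio; non-integer ratios
  are refused rather than silently resampled.
- Agglomerative clustering clamps k to the number of points when a window
  yields very few usable signals, with a log note.

## Known limitations

- Per-pixel classification presumes a stationary subject; translation
  invalidates a window (inherited from the method, not the
  implementation).
- The NumPy training loop is single-threaded BLAS; it is sized for the
  synthetic study (minutes), not for large-scale video corpora.
- Window stitching assumes adjacent windows overlap enough to vote on
  sign; with hop close to the window length, the sign chain can break at
  apnea gaps.
- bpm inside a window is one number; rates that change within a window
  are smoothed by design (the PPI mean).
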