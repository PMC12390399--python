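# Methods

## Signal model

A monostatic UWB impulse radar on a 2.6 m ceiling looks straight down at a
desk.  Each frame records echo amplitude over fast-time delay τ (61 ps per
bin, 288 bins ≈ 17.6 ns ≈ 2.63 m one-way coverage, inside the radar's 3 m
unambiguous range); frames repeat every 12 ms (83.3 Hz slow-time rate).  A
point reflector at one-way range R(t) contributes
`a · p(τ − 2R(t)/c)` per frame, where `p` is the transmitted pulse.  The
pulse is a unit-energy Gaussian-modulated cosine at 3.95 GHz, the midpoint
of the 3.1–4.8 GHz operating band, with its envelope width set so the −6 dB
spectral extent equals 1.7 GHz (`σ_t = sqrt(2 ln 2)/(π·BW) ≈ 0.22 ns`).
Because echoes are rendered by evaluating the continuous pulse at the exact
delay, sub-bin range modulation rotates the carrier phase by `−4π f_c R(t)/c`
and the slow-time spectrum shows the Doppler shift `2 v f_c / c` — the
simulator reproduces the physics the Doppler pipeline measures, not just its
image format.

## Scene simulator

Each recording superposes, per class:

- **coupling** — a strong static return at R ≈ 0.05 m (amplitude 3), the
  cross-antenna leakage every real frame shows near zero delay;
- **clutter** — 2–4 static scatterers at 1.55–2.6 m (desk, floor),
  amplitudes 0.2–0.6;
- **torso** (absent for *empty*) — amplitude ~1, breathing as sinusoidal
  range modulation.  Seated torso height = chair (0.5 m) + torso rise
  drawn from 0.6–0.8 m; standing stature drawn from 1.5–1.8 m.  Under a
  ceiling radar the standing torso is therefore *closer* (≈0.95 m one-way)
  than the seated one (≈1.4 m), which is the main seated/standing cue;
- **limbs** — for *working*: one hand-region scatterer at desk range with
  intermittent bursts (1–3 s of 0.01–0.03 m motion at 2–5 Hz, separated by
  1–5 s pauses), modelling typing; for *stretching*: two arm scatterers
  with slow large sweeps (0.3–0.5 m lifts at 0.2–0.5 Hz).

Inter-participant variability is a sampled profile: torso range offset
±0.10 m, reflectivity 0.7–1.3, breathing rate 0.15–0.35 Hz, breathing
amplitude 2–8 mm, limb-rate scale 0.8–1.2.  White Gaussian noise is added
per sample; its default scale is calibrated once so the single-frame peak
SNR of a unit-reflectivity torso is ≈20 dB.  All draws flow from explicit
seeds (SeedSequence-derived per participant/class), so datasets are
bit-reproducible.

The protocol generator emulates the study design: n participants × four
3-minute posture recordings, plus a 30-minute empty recording partitioned
into n disjoint blocks attributed to pseudo-participants, so the empty
class has per-participant samples without leaking data across
leave-one-subject-out folds.

What the simulator does *not* emulate: multipath and antenna patterns,
extended (non-point) body scattering, real stretching kinematics beyond
"slow and large vs fast and small", multi-person scenes, and environmental
drift.  Passing the end-to-end test therefore shows the pipeline and models
recover class structure from physically plausible radar signals; it is not
evidence about human-trial performance.

## Distance pipeline

Stride-4 sub-sampling gives four 48 ms sub-sequences (exact partition of
the parent).  Windows are 100 frames (4.8 s) with 75 % overlap (25-frame
hop); only complete windows are used.  Filters (all causal, forward-only):

- fast time: 4th-order Butterworth band-pass, 3.1–4.8 GHz at the 16.39 GHz
  fast-time rate — suppresses baseline and out-of-band noise;
- slow time: 5-tap windowed-sinc high-pass (cutoff 1.0 Hz at 20.83 Hz),
  taps re-centred to sum exactly to zero.  The first 4 outputs are dropped
  (100 → 96 frames), which also removes the filter's edge transient;
  a slow-time-constant (static) segment is annihilated *exactly*;
- envelope: absolute value then 2nd-order Butterworth low-pass, 2.0 Hz.

The squashing `x′ = x/(1 + 1.05^(30−x))` suppresses residual low-level
noise (≈0 below ~15, identity above ~60; `squash(30) = 15` exactly; the
exponent is computed as `exp((30−x)·ln 1.05)` with the argument clipped at
±700 to avoid overflow on pathological inputs).  Normalization is per-image
min-max to 0–255 with round-half-up; constant images map to all-zero.
Filter cutoffs/orders are not published; the values above are defaults,
exposed in `FilterBank`.  Causal filtering implies a positive fast-time
group delay of a few bins, so range responses sit slightly after the
geometric bin.

## Doppler pipeline

Hilbert transform along fast time, then a slow-time STFT per 83-frame
(996 ms) window with a Kaiser β=6 taper and 9-frame hop, magnitudes
averaged over all fast-time bins.  The 83 FFT bins are zero-centred and
reduced to 80 by dropping the 2 most negative and 1 most positive extreme
bins — the most symmetric reduction an even count allows (bin width
83.33/83 ≈ 1.004 Hz).  The map is computed once per recording at the native
12 ms rate; the four augmentation offsets of one time window share its
rows.  A 4.8 s excerpt contains ~44 rows (9-frame hop), which are linearly
interpolated to exactly 50; how the original 50-row images were obtained is
unpublished, and interpolation is the stand-in.  Extraction requires the
window to lie within the STFT coverage (one hop of slack at the trailing
edge, since the last window can stop up to 8 frames short of the recording
end); trailing windows of a recording are otherwise dropped by the pairing
code.

## Models

Only the boundary tensors are fixed by the method: `F_d ∈ 128×12×36`,
`F_v ∈ 128×12×20`, ConcatFusion embedding 256, pooled maps 128×4×10,
attention masks 1×4×10 from a 3×3 convolution over the stacked channel-mean
and channel-max maps, fused block input 256×4×10, fused features 512,
AttnFusion embedding 512, five output classes.  Everything else is
configuration: default channel plans 32→64→128 (distance) and 64→128
(Doppler), batch norm + ReLU after each convolution, 2×2 max pooling with
floor division (50→25→12 forces the printed 12×20), MLP heads
256/512→128→5 with dropout 0.3, and one shared attention convolution for
both streams (a per-stream option exists).  `ModelConfig.desk_scale()`
keeps every boundary tensor but narrows the hidden stages to 16→32→128 and
32→128, cutting convolution cost ≈4× for CPU-only runs; it is the
configuration used by the end-to-end tests.

The layers (im2col convolution, batch norm, pooling, attention, Adam,
softmax cross-entropy) are implemented in numpy with manual
backpropagation; every layer's gradient is verified against central finite
differences in the test suite, and a directional-derivative check covers
the assembled model.  Inference is deterministic; training randomness
(init, shuffling, dropout) derives from the per-fold seed, so identical
seeds give identical weights.

## Training and evaluation

Rotation LOSO: fold *i* tests participant *i*, validates *i+1 (mod n)*,
trains the remaining n−2.  Cross-entropy + Adam; after each epoch
validation accuracy is logged; the checkpoint with the highest validation
accuracy is kept (ties → earliest epoch) and training stops after
`patience` epochs without improvement.  Full-scale defaults: lr 1e-3,
batch 64, ≤50 epochs, patience 10.  Metric conventions: precision or
recall is 0 when its denominator is 0, F1 is 0 when precision+recall is 0;
ROC uses post-softmax probabilities, one-vs-rest, pooled over all folds'
test samples, with trapezoidal AUC.  When the test set is exactly
class-balanced, accuracy equals macro recall.

### Desk-scale problem sizes

The end-to-end recovery test uses 4 pseudo-participants × 5 classes × 100
sample pairs (2000 pairs; ~35 s of simulated signal per class and
participant — long enough that every window count is met with all four
offsets represented), the `desk_scale` model configuration, and a reduced
optimization schedule (lr 2e-3, batch 32, 2 epochs, validation accuracy
monitored on a 200-sample subsample).  On this dataset the classes are
strongly separated by design — distinct torso ranges, motion amplitudes
and Doppler bandwidths — and AttnFusion reaches macro F1 ≥ 0.80 across the
4 LOSO folds; ConcatFusion is trained on one fold for comparison.  These
sizes are the package's reference desk-scale experiment; the full protocol
(10 participants, 3-minute recordings, 50-epoch training) runs through the
same code paths via the CLI.

## Known limitations

- Filter coefficients, CNN hidden widths and training hyperparameters are
  not published for the original system; all are defaults here and
  config-exposed, so absolute performance numbers are not comparable to
  the human-trial study.
- Per-image min-max normalization amplifies noise in empty-room images to
  full scale; classification then relies on texture, which the models
  handle but which differs from a global-scale normalization (available as
  a switch through `normalize_to_uint8`).
- The 83→80 bin reduction and the 44→50 row interpolation are documented
  stand-ins for unpublished choices.
- The numpy training stack is single-threaded and CPU-bound; it is meant
  for desk-scale experiments, not full-protocol hyperparameter searches.
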