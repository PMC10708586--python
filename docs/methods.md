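# Methods

This note documents the models implemented in `eegsaliency`, the
conventions and numerical choices behind them, what the synthetic data
generator does and does not emulate, and the package's own resolutions of
design points that were genuinely open.

## Data model

A trial is a 14 × 250 matrix of scalp voltages: the Emotiv EPOC montage
(AF3, F7, F3, FC5, T7, P7, O1, then AF4, F8, F4, FC6, T8, P8, O2 — left
hemisphere first) sampled at 128 Hz for ~2 s. Recordings longer than 250
samples are trimmed to the **first** 250 (which 250 of the ~256 recorded
samples the upstream corpus used is unknowable; first-250 is the package's
fixed choice). Each channel is standardised to zero mean and unit variance
per trial; channels with standard deviation below 1e-8 map to all-zeros.

On disk the package reads and writes the public MindBigData line dialect:
one tab-separated line per (event, channel) with comma-separated samples.
Events missing any of the 14 channels are dropped with a warning rather
than zero-filled — a conservative rule that never fabricates signal.
Values are written with full `repr` precision so a write/read round trip
is bit-exact. GAN-generated records carry a provenance flag, serialised as
a `-SYN` suffix on the device field.

## Classifier

Three convolution stages, each: depthwise time-axis convolution (kernel
1 × 5, stride 1, same padding, so the 14 electrode rows are a shared
spatial axis and the filter count — 14/10/10 full-scale — forms the
leading activation axis), leaky rectifier (slope 0.1), batch
normalisation, dropout 0.2. Then flatten (10 · 14 · 250 = 35 000),
dense 3500 → dense 2500 → dense 10 with log-softmax. The 2500-long
penultimate activation is the feature vector handed to the generator.

Choices worth noting:

- **Batch normalisation** has no learned affine by default (an optional
  affine is available); ε = 1e-5; inference uses running averages with
  momentum 0.9. Statistics pool per feature over the batch (and over
  space for conv activations).
- **Hidden dense activations.** The two hidden dense layers use the same
  leaky rectifier as the conv stages; without one they would collapse
  into a single linear map.
- **Training**: cross-entropy on the log-softmax outputs, plain SGD with
  learning rate 1e-3 and L2 weight decay 5e-5, batch size 32 (the batch
  size is a package default; nothing upstream fixes it). Initialisation
  is uniform ±1/√fan_in from a per-network seed; training is fully
  deterministic given the seed.
- **Profiles.** `paper`: the sizes above (~122 M parameters — forward
  pass scale on a laptop, not training scale). `desk`: filters 4/4/4,
  dense 128/64 (feature length 64), identical stage structure, trainable
  in seconds-to-minutes on one CPU. The desk profile only shrinks sizes.

Cross-validation is stratified k-fold (scikit-learn's `StratifiedKFold`,
shuffled with the run seed); per-fold accuracy/precision/recall/F1/kappa
plus mean ± sd are reported.

## Saliency GAN

Generator: dense 2500 → 100 (no bias, 250 000 weights), dense 100 →
20 000 (no bias, 2 000 000 weights), reshape to an 8-channel 50 × 50
grid, four 4 × 4 transposed convolutions with 6 kernels and strides
2, 3, 1, 1 (spatial chain 50 → 100 → 300 → 300 → 300), then a 2 × 2
stride-1 valid convolution to a single 299 × 299 channel. All
activations are leaky rectifiers (slope 0.1). Transposed convolutions
are bias-free (matching the printed 250 000 / 2 000 000 / 768 counts);
the final convolution carries a bias (25 weights). Where the printed
per-layer counts are internally inconsistent (768 repeated for 6 → 6
stages whose kernel arithmetic gives 576; 33 for the final convolution
where the arithmetic gives 25), the kernel/channel arithmetic wins.

Transposed convolutions use output = input × stride semantics
(zero-insertion dilation, total padding stride + kernel − 2 per axis).
The final 2 × 2 valid convolution is stride 1: a stride-2 layer cannot
produce a 299-wide output from the 300-wide penultimate grid, and the
odd side 299 is what makes the discriminator chain below consistent.

Discriminator: three 4 × 4 stride-2 same-padded convolutions with 2
kernels each (299 → 150 → 75 → 38; bias-free, 32 weights in the first),
dropout 0.2 after each, flatten (38 · 38 · 2 = 2888) and a biased dense
unit (2889 weights) with sigmoid output.

**Training objective.** One discriminator step and one generator step per
batch, Adam at lr 1e-4. The discriminator minimises binary cross-entropy
on a combined real+fake batch (real = 1, fake = 0; probabilities clamped
at 1e-7). The generator minimises the non-saturating adversarial loss
−mean log D(G(y)) **plus** a pixel-wise binary cross-entropy between its
output and the paired target map (weight `recon_weight`, default 1.0,
clamped at 1e-3 with straight-through boundary gradients). The
reconstruction term is the package's resolution of a genuine gap: the
discriminator sees only images, so a purely adversarial generator could
map any feature vector to any realistic map — per-pair SSIM/CC of the
kind this pipeline is evaluated on would be unreachable in principle
(and empirically plateaus near zero at desk scale). Pixel-wise BCE is
the natural pairing loss for unit-range images and stays inside the
stated binary-cross-entropy loss family. Target maps are rescaled to
unit peak before training so the generator works on image-like
intensities; generated maps are clamped at 0 when interpreted as
saliency.

**Desk profile**: feature length 64, dense 32/512, reshape (8, 8, 8),
strides 2, 4, 1, 1 (8 → 16 → 64 → 64 → 64 → 63), 4 kernels per stage;
discriminator input 63 (chain 63 → 32 → 16 → 8, flatten 128). Same
stage structure, minutes-scale training.

## Transfer and fine-tuning

`transfer_weights` copies every parameter tensor exactly (destination
forward passes equal the source bit for bit) and refuses mismatched
architectures, naming the offending parameters. Fine-tuning to the
original stimulus images re-runs the same adversarial loop at 0.1 × the
base learning rate with **both** networks trainable (whether the
discriminator should also be tuned was open; tuning both keeps the
adversarial game balanced). Stimulus images share the canonical side
(299, desk 63) so no architecture change is needed at transfer time.
The fine-tune history tracks generator/discriminator losses plus mean
SSIM and CC against the targets on a fixed probe subset each iteration.

## Augmentation GAN

One generator/discriminator pair per digit class. Generator: a
100-dimensional standard-normal latent (the upstream input is unstated;
this is the package's choice) → dense to an 8-channel 7 × 125 grid →
two stride-1 1 × 4 transposed convolutions (8 kernels) → one stride-2
transposed convolution to the 14 × 250 signal grid, single output
channel, leaky rectifier slope 0.3 throughout. The final stage uses a
2 × 4 kernel rather than 1 × 4: with a height-1 kernel the stride-2
height upsampling would zero-stuff every other electrode row. A printed
30-channel output is reduced to 1 — a 14 × 250 × 30 tensor is not an
EEG signal. Discriminator: three 1 × 4 convolutions (6 kernels, strides
1, 2, 1, dropout 0.2; 14 × 250 → 7 × 125 → 7 × 125), flatten 5250,
biased dense unit, sigmoid.

This GAN trains on the adversarial loss alone (signals are signed, so
the [0,1] pixel reconstruction term does not apply), Adam lr 1e-3 as the
package default (nothing upstream fixes this GAN's optimiser), desk
default 300 iterations versus the reference schedule of 9000.
`augment_dataset` appends n_sets generated signals per class with
provenance flags and an updated manifest (e.g. 50 sets × 10 classes on
a 9120-record base → 9620).

## Synthetic world

`generate_eeg_dataset` draws, for class k, records whose channel c is
amp[k, c] · sin(2π f_k t + φ_c + ψ_r) plus N(0, noise_sd²) noise: f_k are
the class frequencies (default an even 2–29 Hz spread, far below the
64 Hz Nyquist limit), φ_c are channel phases fixed by the seed, ψ_r is a
per-record global phase. Class identity is therefore a spectral peak and
separability is the amplitude/noise ratio; the default noise_sd = 0.5
gives a clearly learnable 2:1 ratio, and the desk experiment uses 0.3.
Stimulus images are white 5 × 7 bitmap glyphs (padded to a 7 × 7 cell
grid) on black, nearest-neighbour upscaled; saliency ground truth is the
Gaussian-blurred glyph mask normalised to unit sum (blur σ defaults to
image_size/30).

What this does **not** emulate: real EEG physiology (event-related
potentials, 1/f background spectra, artifacts, inter-subject
variability), real attention-model saliency, or anti-aliased digit
rendering. A green learning-behaviour test therefore establishes that
the implementation can extract a planted, spectrally clean class signal
and regress paired targets — not that the architecture reaches any
particular accuracy on real recordings.

## Metrics

- **SIM**: both maps normalised to sum 1, then Σ_j min(SM_j, FM_j).
- **SSIM**: uniform L × L windows (default 11), stride 1, valid
  positions only; per window (2μ_mμ_n + k₁)(2σ_mn + k₂) /
  ((μ_m² + μ_n² + k₁)(σ_m² + σ_n² + k₂)) with k₁ = (0.01 K)²,
  k₂ = (0.03 K)², unbiased variance/covariance estimates (matching
  scikit-image's uniform-window implementation, which the tests
  cross-check to 1e-10). K defaults to 255 for integer images and 1.0
  for unit-range floats.
- **CC**: Pearson correlation over all pixels.
- **Classification**: one-vs-rest TP/TN/FP/FN per class. Two F1
  conventions are carried: the arithmetic mean (precision + recall)/2 —
  the pipeline's parity default — and the standard harmonic mean,
  reported as `f1_harmonic`. Cohen's kappa uses the binary form
  2(TP·TN − FN·FP) / [(TP+FP)(FP+TN) + (TP+FN)(FN+TN)], macro-averaged
  over classes (how a single kappa should be formed for 10 classes was
  unspecified upstream). Metrics with zero denominators surface as NaN
  and are listed in an `undefined` field rather than coerced to 0,
  which would silently deflate or inflate macro averages.

## Desk experiment defaults

3 classes, 12 trials per class, noise_sd 0.3, 63-pixel images; 3-fold
stratified CV and a 25 % held-out split; classifier 300 iterations;
saliency GAN 150 iterations; fine-tune 80 iterations at 0.1 × lr. These
are runtime-scaled defaults (the full run takes ~2.5 minutes on one
CPU); the dedicated learning-behaviour tests use longer schedules (500
GAN + 250 fine-tune iterations) where the SSIM improvements are robust.

## Known limitations

- The full-scale (paper-profile) classifier is forward-pass scale only
  in this package; its ~122 M-parameter dense layer makes CPU training
  impractical, and the reference accuracy figures (95.4 % etc.) require
  the real corpus and long training — they are out of scope here.
- At desk iteration counts the augmentation GAN does not yet place its
  spectral peak at the class frequency; the honest desk-scale property
  (asserted in the tests) is that training moves the generated mean
  spectrum toward the real class spectrum. Recovering the oscillation
  itself needs schedules near the reference 9000 iterations.
- SSIM rewards flat agreement: an untrained generator emitting
  near-zero maps scores a deceptively decent SSIM against mostly-dark
  targets. Before/after comparisons in the tests therefore train long
  enough to cross that baseline, and CC (which ignores offsets and
  scale) is reported alongside.
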