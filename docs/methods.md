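# Methods

## Data model

A preprocessed trial is a 300 x 9 real matrix: 5 s at 60 Hz across nine
kinematic degrees of freedom — T8 trunk-marker position x/y/z in
centimeters, T8 z-orientation and shoulder (x/y/z) / elbow (x/y) angles in
radians, in that fixed channel order. Shorter recordings are extended by
repeating the final sample; longer ones are cropped to the first 300
samples (movement onset sits at trial start in the underlying protocol, so
the informative segment is the prefix). Source units default to meters and
degrees, the common motion-capture export convention, and are rescaled on
load.

Labels combine 10 reach-and-return tasks with 3 impairment groups into 30
classes, `code = task_index * 3 + group_index`. Stroke survivors split at
an FMMA-UE score of 42: strictly above is "mild", 42 and below joins the
pooled moderate+severe group. The boundary assignment matters because the
moderate cohort's median score is exactly 42; sending 42 to the pooled
group keeps that cohort intact. The finer clinical bands (severe < 25,
moderate 25–53, mild > 53) are kept as a separate utility.

## Movement simulator

`simulate_trial` composes, per channel: a resting-posture baseline, a
reach-and-return envelope (minimum-jerk rise 10t³ − 15t⁴ + 6t⁵ to peak,
minimum-jerk fall back), a per-task amplitude template scaled by
impairment-dependent gains, and additive noise.

- **Templates**: ten fixed 9-vectors of peak excursions (a few cm of trunk
  motion, 0.1–1.6 rad of arm motion), chosen to be mutually distinct so
  the tasks are separable in range-of-motion space at control level and a
  classifier has a learnable signal at desk scale.
- **Group gains**: trunk channels multiply by 1.0 / 1.5 / 2.2 and arm
  channels by 1.0 / 0.80 / 0.55 for control / mild / moderate+severe.
  These orderings encode the two phenomena the synthesis must reproduce —
  compensatory trunk displacement grows with impairment while active arm
  range shrinks — and are enforced as parameter invariants.
- **Timing**: movement duration is N(3.5 s, 0.4 s) clipped to [1.5 s, 5 s]
  with a uniformly drawn onset inside the window, so every noise-free trial
  starts and ends at baseline.
- **Noise**: white Gaussian noise lowpass-filtered at 4 Hz, with
  per-channel SDs of 0.2 cm (positions) and 0.01–0.025 rad (angles). The
  4 Hz cutoff is deliberate: raw simulated data keep some energy above
  2 Hz, so the spectral loss and the 2 Hz post-filter have a measurable
  effect. Noise-free envelopes keep ≥ 95 % of their power below 2 Hz.

Each trial draws from a counter-derived substream
(`SeedSequence([seed, class, index])`), making datasets reproducible and
order-independent.

The simulator emulates class structure, impairment-dependent compensation
and smoothness; it does not model joint limits, multi-joint coupling,
subject identity, or the absolute amplitudes of any real dataset. Passing
tests on simulated data therefore demonstrate that the pipeline's
machinery works and recovers planted structure — not that the GAN matches
real post-stroke kinematics.

## GAN

Generator and discriminator follow the recipe described in the README. The
published hyperparameters are Adam lr 0.0003 with beta1 0.5, dropout 0.4,
generator Conv1D filters 256/128 with kernel 15, and a final 9-filter
convolution; sizes the recipe leaves open are exposed with these defaults:
noise_dim 100, label embedding 16, batch 32, 500 epochs,
minibatch-discrimination 8 kernels x 4 dims, discriminator filters 128/256
with the label broadcast over 4 constant channels. Channels are
standardized to zero mean / unit variance over the training set before
training (cm and rad scales would otherwise dominate the losses) and
de-standardized at sampling. Batch norm uses running statistics and
dropout is disabled at sampling, so generation is deterministic given z.

**Spectral loss.** The loss compares FFT *magnitude* spectra (a complex
difference would be phase-sensitive, and circular time shifts of a reach
should not be penalized) and is the mean squared difference, weight
λ = 1.0 added to the generator's adversarial loss. Two pairings are
implemented:

- `paired` (default): fake sample i is compared with the real sample i of
  the minibatch, which shares its class label. This keeps the loss
  class-consistent.
- `batch_mean`: batch-average real spectrum vs batch-average fake
  spectrum. Because minibatches mix classes, this variant pulls every
  class toward the batch-average spectrum; on the two-class toy problem it
  measurably degrades conditional recovery at longer training, which is
  why `paired` is the default.

The spectral term is evaluated on an *inference-mode* generator pass
(dropout off, running batch-norm statistics) with its gradient added to
the adversarial gradient from the training-mode pass. Evaluating it on the
dropout-noised training pass instead makes the generator compensate for
noise that is absent at sampling time, and its sampled output comes out
with systematically shrunken amplitudes.

**Minibatch discrimination** excludes the j = i term, so a batch of one
yields zero features and identical samples yield exp(0) per other sample.
During training, discriminator real and fake passes run separately (the
similarity pool never mixes real with fake).

Degenerate inputs: classes absent from the training data are excluded from
conditioning and rejected at sampling; non-finite losses abort training
with the epoch diagnostics.

**2 Hz filter**: zero-phase (forward–backward) 4th-order Butterworth,
applied per channel. Forward–backward filtering squares the magnitude
response, so the stopband attenuation at 5 Hz comfortably exceeds 20 dB
while a 0.5 Hz component passes within 2 %.

## Realism statistics

Range of motion (max − min per channel) is compared between real and
synthetic trials per (task, channel, group) cell with a two-sided *Welch*
t-test — variances of real and generated ROM distributions have no reason
to match, so the unequal-variance form is the safer default (Student's
form is a config switch away via scipy). Cells with fewer than two trials
per side are flagged rather than tested; both-constant samples get p = 1
on equal means. No multiplicity correction is applied: the grid is
reported raw, bold-at-0.05 style. The grid pools trials, not subjects.

High-band power uses a Parseval-consistent one-sided periodogram
(interior rfft bins doubled), excluding DC, pooled over samples and
channels. t-SNE embeds flattened per-channel-standardized trials
(2700-dim) with perplexity min(30, N/4) and PCA initialization.

## Classifier and experiment

The FCN is Conv1D(64, k3, ReLU) → pool2 → Conv1D(128, k3, ReLU) → pool2 →
flatten → dense(100, ReLU) → dropout(0.5) → softmax, with 'same'
convolution padding so 300 → 150 → 75 and the flatten width is 9600.
Epochs and batch size are not part of the published recipe; defaults are
100 and 32. The default target is the 10 tasks; the 30-code space is a
parameter away (`target="class"` in `run_experiment`).

The ratio sweep uses stratified 5-fold CV (per-class round-robin dealing
with a random fold offset; classes smaller than k are still dealt).
Within each fold the GAN trains on the training portion only — training
it on all real data would leak held-out information into the synthetic
samples — and one GAN bundle serves all ratio conditions of that fold for
comparability (a `gan_global` switch mimics the leaky alternative).
Synthetic counts are `round(n_real * synth/real)`, allocated per class
proportionally to real class counts with largest-remainder rounding, and
pass the 2 Hz filter before joining the training set. Test folds contain
real trials only, asserted from provenance tags. Metrics are
support-weighted precision/recall/F1 plus accuracy; support-weighted
recall equals accuracy identically, a useful invariant for consistency
checks. The ± values are across-fold standard deviations. Every stage
seeds from a single `SeedSequence`, so a run is bit-reproducible.

## Desk-scale configurations

The defaults above describe the full-size recipe. Tests and
`scripts/acceptance.py` run reduced configurations chosen once for
single-CPU execution:

- toy GAN (two-class sinusoids, length 64, one channel): noise 16,
  embedding 4, filters 32/16, kernel 9, discriminator 16/32, batch 32;
  conditional recovery is evaluated after 200 epochs.
- trial-scale GAN: noise 32, embedding 8, reshape 75 x 8, filters 16/8,
  kernel 9, discriminator 8/16, batch 64, 10 epochs.
- FCN: filters 8/16, dense 32, 10–30 epochs, batch 64.
- experiment data: 20 simulated trials per class (600 total), 5 folds.

The λ > 0 vs λ = 0 comparison is evaluated at 40 toy epochs: the excess
high-frequency energy of a plain conditional GAN is a mid-training
phenomenon on this toy — with enough epochs both variants converge to
smooth outputs and the contrast fades — so the comparison targets the
regime where the artifact the loss exists to remove is present.

## Known limitations

- The simulator's linear ROM separability makes the classification task
  easier than real post-stroke data; absolute accuracies on simulated data
  are optimistic and only the *direction* of the augmentation effect is
  meaningful.
- The numpy networks are CPU-bound; full-size (256/128-filter, 500-epoch)
  GAN training is supported but slow, and the shipped experiments use the
  reduced configurations above.
- GAN training quality is seed-sensitive at desk scale; the package
  reports per-seed outcomes rather than a single run where that matters.
- Native motion-capture container formats (MVN/MVNX) are out of scope; the
  reader expects the documented CSV dialect.
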