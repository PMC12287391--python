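# Methods

This note documents the models and procedures implemented in `acti2img`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions adopted where a
design question was genuinely open.

## Data model

A recording is a per-participant series of non-negative integer activity
counts on a strictly increasing minute grid, with a binary diagnosis label
(condition = 1, control = 0). Gaps in the minute grid are detected at I/O
time and retained — no imputation happens on read, so writing a recording
back reproduces the file exactly. Timestamps are timezone-naive local
time, as in the source CSVs. How first/last partial days are treated is a
segmentation concern: windows tile from the first epoch by default, with
an optional midnight alignment (`align="midnight"`) that prepends the
pre-recording portion of day one as gap epochs.

## Segmentation

Windows of 180 / 60 / 20 minutes (3 h, 1 h, 20 min) cut each recording
with stride equal to the window (non-overlapping) by default; overlap is
available via `stride_minutes`. A gapless day therefore yields 8 / 24 / 72
windows, and combining all three sizes augments a day to 104 windows.
Windows whose gap fraction exceeds `max_gap_fraction` (default 0.1) are
dropped and counted; gap epochs inside kept windows are filled with zero,
matching the "no movement" semantics of a count of zero. Every window
inherits its participant's label — with multi-day labels this is forced,
but it is worth stating because it is what makes the segment-level split
optimistic (see Evaluation).

## Markov Transition Field

Quantile binning uses empirical quantiles at levels k/Q, k = 1..Q−1, with
Q = 8 by default — fine enough for overdispersed count data, coarse enough
that a 20-minute window still populates the transition matrix. Intervals
are right-closed: a value equal to an edge falls in the lower bin. This
tie rule is load-bearing for count data: zero-heavy series routinely place
quantiles at the minimum, and a left-closed rule would merge the zero mass
with everything above it (the two-level alternation 0,1,0,1,0 — whose
field must be a 0/1 checkerboard — would collapse to a single bin).
Duplicate edges and edges at or above the series maximum are dropped, so
the effective bin count can be smaller than Q; a constant series
degenerates to one bin with a warning, never an error.

Transitions between consecutive bins are counted and row-normalized; rows
with no observations become uniform 1/Q. Two orientations are exposed:
`destination` (default) counts "a point in bin j followed by a point in
bin i" into `w[i, j]`, i.e. rows indexed by the destination bin;
`source` is the more common convention with rows indexed by the source
bin. Both are verified against a brute-force oracle; the field value at
(i, j) is `W[bin(x_i), bin(x_j)]` either way, so the choice matters only
for asymmetric dynamics.

Bin edges can be fitted on the segment itself or on the whole source
recording. The pipeline default is per-recording
(`binning_scope="recording"`): per-segment edges re-normalize every
window to its own range, which erases where the window sits in the
participant's overall intensity profile — a night window and a day window
then look alike up to rank structure — whereas recording-level edges let
bin identity carry circadian amplitude information into the field. On the
synthetic task this is worth several points of held-out accuracy;
per-segment fitting remains available (`binning_scope="segment"`) and is
the natural choice when single windows are encoded in isolation.

Fields larger than 128 pixels are shrunk with the uniform blurring kernel
{1/m²} over non-overlapping m×m patches, m = ceil(n/128) — a 180-minute
window becomes 90×90 — then bilinearly resized to 64×64 and min-max
mapped to [0, 1]. A constant image maps to all zeros, with a warning.
64×64 keeps the CNNs trainable on one CPU; a Gaussian blur kernel is not
provided because the uniform kernel is exactly the {1/m²} average and the
difference is immaterial after resizing.

## GAF and RP

GAF reduces the window by piecewise-aggregate approximation (block means
over an even index partition) to at most 128 points, rescales min-max to
[−1, 1] (a constant window maps to 0, i.e. angle π/2, with a warning),
maps to angles φ = arccos(x), and forms cos(φᵢ+φⱼ) (GASF, the default
variant) or sin(φᵢ−φⱼ) (GADF). GASF satisfies the closed form
xᵢxⱼ − √(1−xᵢ²)√(1−xⱼ²), which the tests assert.

RP is the pairwise distance matrix |xᵢ−xⱼ|, kept unthresholded by default
so no arbitrary ε is introduced; the thresholded 0/1 variant is available.
Both encoders share the blur/resize/normalize tail of the pipeline.

## Classifiers

The two architectures are fixed: `simple` is two Conv2D(32 filters, 5×5,
same padding, ReLU) + MaxPool(2×2) blocks, then Flatten → Dense(256,
ReLU) → Dense(1); `deep` adds a third block and 50 % dropout after each
pool and before the output. Training minimizes binary cross-entropy with
Adam (β₁ = 0.9, β₂ = 0.999). The implementation is plain NumPy —
convolution as im2col matrix products, inverted dropout, bias-corrected
Adam — which keeps the package dependency-light and every random draw
(init, shuffling, dropout) under one integer seed, so training is exactly
reproducible on a single CPU thread.

Defaults: learning rate 1e−3 with per-epoch multiplicative decay 0.85,
batch 32, 10 epochs. The decayed schedule converges monotonically on the
synthetic task, where a constant rate oscillates around the optimum late
in training; 10 epochs is past the plateau at the default problem size.
The sigmoid threshold is fixed at 0.5. Class imbalance is handled by
seeded random undersampling of the majority class, applied to the
training split only (leakage-safe); class weighting would be the natural
alternative but undersampling keeps the loss untouched.

## Evaluation

Accuracy, precision, recall and F1 are computed from TP/FP/TN/FN with the
condition group positive, reported as percentages. Precision with no
positive predictions (or recall with no positive labels) is reported as
undefined with a flag, and F1 is then 0. Cohort descriptives are sample
skewness and excess (Fisher) kurtosis of pooled counts per group — excess
kurtosis because activity counts are compared against a normal baseline
at 0 — plus a two-sided Mann–Whitney U p-value on per-participant mean
counts; the rank test is used because counts are grossly non-normal, and
the test is run at participant level to respect the dependence of epochs
within a person.

Two split modes: `segment_level` (stratified random split of windows —
mirrors protocols that split "the data", but windows from one participant
can land on both sides, leaking person-specific patterns) and
`participant_level` (whole participants per side; the honest protocol).
The default is segment-level so that the leakage gap can be measured;
every report of a segment-level run carries a flag saying so, and the
reproduction script reports both numbers side by side.

## Synthetic cohort generator

The generator emulates the features of case–control actigraphy that the
pipeline is supposed to detect, not the marginal distributions of any real
dataset. Background intensity is a clipped sinusoid,
λ(t) = A·max(0, sin(2π(t − t_rise)/1440)) with rise at 06:00, plus a small
nighttime baseline (5 % of A) representing residual movement during
sleep; counts are Poisson with gamma-mixed rates (negative-binomial
behaviour, dispersion shape 5), and night epochs are zeroed with
probability 0.9 (sleep stillness). The baseline exists so that the
zeroing probability is a meaningful parameter; without it the clipped
sinusoid is already zero all night.

The condition group (default amplitude 120 vs 300 counts/min at peak)
additionally receives daytime rest episodes (Poisson 6/day, geometric
duration, mean 40 min, zeroed activity — psychomotor retardation) and
wake/agitation bursts at any hour (Poisson 20/day, geometric duration,
mean 10 min, Poisson magnitude 4× the condition amplitude, applied after
night zeroing because a burst is actual movement). Bursts of several
minutes are the clinically typical wake-bout length in fragmented sleep,
and nocturnal disturbance is deliberately prominent: in the real
case–control data night periods are among the most discriminative. The
burst and rest mechanisms jointly produce the documented group contrasts:
lower condition daytime mean, heavier condition right tail (higher
skewness), and separability of per-participant daytime means under a rank
test at n = 30/30.

Per-participant streams derive from `SeedSequence([cohort_seed, index])`,
so cohorts are bit-identical across calls and participants are
independent. What the generator does **not** emulate: inter-daily
variability of rhythm phase, weekday/weekend structure, device non-wear
artifacts, medication effects, or the real datasets' exact marginals.
Passing the end-to-end test therefore shows the pipeline can recover a
known circadian/eventstructure contrast at realistic noise levels — not
that it attains any particular accuracy on Depresjon or Psykose.

## Problem sizes and runtime

The default experiment (and the reproduction script) uses 30 + 30
participants × 3 days × 180-minute windows = 1440 segments, 64×64 images,
and the simple CNN for 10 epochs; one run is a few minutes on one CPU,
and the script's three replicate seeds plus a participant-level run total
roughly a quarter of an hour. These sizes are the package's defaults, not
limits — every knob is config-exposed.

## Known limitations

* The real-data replication path (`acti2img replicate`) depends on
  locally downloaded Depresjon/Psykose copies and unreported protocol
  details (split mode, epochs, window mix), so its numbers should be read
  as a replication attempt.
* The attention-style pooling sometimes mentioned alongside this family
  of pipelines has no published definition and is not implemented.
* Only first-order (one-step) transition statistics are encoded; no
  multivariate channels.
* The NumPy CNN is single-threaded by design; it trades throughput for
  exact reproducibility and zero framework dependencies.
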