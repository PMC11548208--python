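# Methods

## The task and the model

`headseg` treats movement annotation as binary semantic segmentation of a
3-channel head-orientation time series: every sample is labelled moving or
still. The segmenter is a 1D-UNet. The encoder has five blocks; each applies
two kernel-9, stride-1, padding-4 convolutions (so length is preserved),
each followed by batch normalisation and ReLU, then a size-2 max-pool.
Level widths are 16, 32, 64, 128 and 256 channels. The bottleneck is two
more conv–BN–ReLU layers; its width is not fixed by the level list, and the
package follows the standard U-Net convention of doubling the deepest width
(512). The decoder mirrors the encoder: ×2 upsampling (nearest-neighbour by
default, transposed convolution selectable), concatenation with the
same-scale encoder features, and two conv–BN–ReLU layers. A kernel-1
convolution to one channel plus a sigmoid produces per-sample movement
probabilities. Five poolings mean window lengths must be divisible by 32.
Convolutions feeding ReLUs use Kaiming initialisation; the sigmoid head uses
Xavier; both are drawn from a seeded generator so builds are bit-identical.

The network, its backpropagation and the optimiser are written in NumPy
(convolutions evaluated as GEMM over im2col patches). The analytic gradients
are verified against central finite differences in float64 in the test
suite, for both upsampling modes.

Training minimises the soft dice loss
`1 − (2Σpt + s)/(Σp + Σt + s)` (smoothing s = 1e-6, a conventional
stabiliser) with Adadelta at learning rate 0.1, batch size 64. Adadelta's
decay and epsilon are package choices: rho = 0.95 (the method's original
recommendation) and eps = 1e-5. Framework defaults for eps span 1e-8 to
1e-5; the larger value shortens Adadelta's well-known cold start, in which
the update accumulator needs many steps to grow from zero — decisive when a
desk-scale run performs only a few hundred updates.

## Synthetic sessions

No public recordings exist for this protocol, so the generator emulates the
experimental design directly: 60 instructed movements per session over
3 blocks, each trial a 3 s countdown followed by a 7 s response window; the
conditions cross 3 rotation axes (up/down, left/right, lateral bend),
2 speeds and 3 movement types (half: excursion that holds; complete:
there-and-back; repeated: several oscillations). 3 × 2 × 3 = 18 conditions
cannot tile 60 trials exactly, so the grid is cycled: each condition occurs
3 or 4 times per session (balance within ±1).

Quantities the protocol leaves open are fixed once as config defaults:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 30 Hz | standard webcam frame rate; all code is fs-parametric |
| inter-trial gap | 2 s | keeps trials separated without stretching the session |
| onset jitter | U[0, 1.5] s | movements never start exactly on the cue |
| movement amplitude | 30° × U[0.8, 1.2] | comfortable instructed head rotation |
| slow durations (half/complete/repeated) | 3 / 4 / 5 s | fits the 7 s window with jitter |
| fast movements | ×0.5 duration, ×0.5 rise time | makes speeds separable |
| sample noise | Gaussian, sd 0.5° | pose-estimator jitter |
| baseline drift | 1 sinusoid/channel, 2° peak, 120 s period | slow posture drift |

Waveforms are raised-cosine (smooth, band-limited, endpoint-exact, so tests
can assert amplitudes exactly). Half movements change posture, so their
direction alternates to keep the baseline bounded; all channels are clipped
at ±90° (never reached under defaults) with a warning. Events rasterise to
half-open `[onset, offset)` sample intervals so abutting events tile without
double-counting.

What the generator does **not** emulate: pose-estimator failure bursts and
occlusions (the pose module handles these, but cohorts are generated fully
valid), spontaneous non-instructed movements, facial-expression trials,
multi-axis compound movements, and any fNIRS signal content. Passing the
synthetic experiment therefore shows the pipeline recovers annotations under
the stated noise model, not that it matches human annotators on real video.

## Inference and annotation

Whole sessions are segmented by tiling fixed-length windows (default 320
samples ≈ 10.7 s, spanning a full trial), averaging probabilities where
windows overlap, binarising at 0.5 (the sigmoid midpoint; configurable), and
cropping edge padding. Signals not a multiple of 32 samples are edge-padded
and cropped back. The default inference stride is one full window; the
study-scale preset uses a half-window stride, whose overlap averaging
measurably improves behaviour at window boundaries (held-out J 0.81 → 0.83
in the calibration run).

Binary masks convert to event tables by taking maximal runs of ones;
optional post-filters merge gaps shorter than 0.2 s and drop events shorter
than 0.2 s (both off during evaluation so metrics reflect the raw model).
Annotations resample onto other timebases (e.g. the 10.17 Hz fNIRS grid) by
rounding event ends to the nearest output sample boundary while keeping at
least one sample per event: total masked duration is preserved to within one
output sample per event and no event at least one output sample long is
lost. A `conservative` mode instead marks every output sample that overlaps
a masked interval at all — preferable when the mask feeds artifact
*rejection*, at the cost of over-marking event ends.

## Evaluation

Agreement with reference annotations is the Jaccard index over
positively-labelled samples. Scores are computed per reference trial inside
an evaluation window — the annotated event extended by a 1 s margin on each
side — so misses, boundary spillover and nearby false alarms all count
against that trial. (The margin is anchored on the annotation rather than
the stimulus schedule because real recordings carry only annotations.) Two
masks that are both empty in a window score 1, avoiding 0/0; the protocol
guarantees every trial contains movement, so this convention never fires in
practice. Partition scores average per-trial scores; a pooled mode
(summing intersections and unions before dividing) is available behind a
flag. Confidence intervals are seeded percentile bootstraps over trials:
resample trials with replacement (10 000 times by default), take each
resample's mean, report the 2.5th and 97.5th percentiles.

## The desk-scale experiment

`headseg.pipeline.scaled_config` reproduces the study shape — 10 training
and 5 held-out participants under the defaults above — at single-CPU scale:
40 training windows per session (of ~134 available at 50 % overlap),
60 epochs, half-window-stride inference. The window count and epoch budget
were calibrated on training-loss convergence: too few windows per session
(12) let the network memorise the trained window positions (J ≈ 0.97 on
those windows but ≈ 0.66 on full sessions), while 40 windows per session
restore generalisation; 60 epochs leaves the loss near its floor. A full
run takes roughly 9 minutes and reaches held-out J ≈ 0.87, with the
movement-type ordering repeated > complete > half — brief partial movements
offer the least overlap mass and are hardest to delineate, the same
qualitative pattern expected of the full-scale recipe (batch 64, lr 0.1,
1000 epochs on all windows).

## Numerical and degenerate-input choices

* Output probabilities are clipped to (1e-7, 1 − 1e-7), keeping them in the
  open interval even when float32 sigmoids saturate.
* Robust per-session normalisation (median / 1.4826·MAD per channel;
  scale 1 for constant channels) is applied before training and inference by
  default; it removes between-participant baseline-posture differences.
* Invalid pose samples: interior gaps ≤ 0.5 s are linearly interpolated and
  marked valid; longer gaps get interpolated values but stay flagged;
  leading/trailing gaps take the nearest valid value. A signal with zero
  valid samples is an error.
* Empty event lists rasterise to all-zero masks; overlapping reference
  events are an error, not silently merged.
* Training is single-threaded deterministic: given identical config and
  seed, cohort, initial weights, batch order, bootstrap draws — and hence
  the report files — are byte-identical.

## Known limitations

* The synthetic noise model is i.i.d. Gaussian plus slow drift; real pose
  estimators produce heavier-tailed, temporally correlated errors.
* One model segments all three axes jointly (`in_channels=3`); a
  single-channel model can be configured (`in_channels=1`) but the package
  provides no turnkey per-axis pipeline and has not compared the two.
* The NumPy training loop is CPU-bound and practical to a few thousand
  window-epochs; full-scale (1000-epoch, all-window) training is expressible
  but slow.
* Evaluation windows derive from annotated events, so long annotation-free
  stretches contribute to no trial's score; whole-session pooled Jaccard is
  available via the pooled flag if that matters.
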