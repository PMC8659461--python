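# Methods

## Problem setting

The package classifies a driver's cognitive state into two classes —
baseline driving (class 0) versus driving with an auditory one-back task
(class 1) — from eye-movement signals derived from facial video. The
emulated study design is 30 subjects, each driving 12 one-minute scenario
segments, 6 per class, recorded at 30 samples/s; non-overlapping 30 s
windows give 720 labeled windows (360 per class). Subject fatigue is out
of scope; the labels reflect only the presence of the secondary task.

## Synthetic gaze generation

Real recordings of this design are not redistributable, so the study
conditions are emulated by a generative model whose defaults are fixed
once and used everywhere (tests, examples, the experiment pipeline).

A trace alternates **fixation epochs** and **saccade epochs**:

* Fixation durations are truncated-normal draws (floor: 2 samples).
  During a fixation, the position holds an anchor plus AR(1) jitter with
  autocorrelation ρ = 0.9 and stationary standard deviation
  `fixation_jitter_sd`. The AR(1) form emulates slow ocular drift and
  keeps jitter-induced sample-to-sample speeds far below saccadic speeds;
  with i.i.d. jitter roughly 10 % of fixation samples would exceed
  3 × jitter-sd × fs, which would make any velocity threshold ill-posed
  at these sampling rates.
* A saccade follows a fixation with probability
  `min(1, saccade_rate × (mean fixation + mean saccade duration))`
  (Bernoulli thinning), so the realised saccade rate honours
  `saccade_rate` up to the geometric cap; `saccade_rate = 0` yields one
  uninterrupted fixation. Saccade amplitudes are truncated-normal draws;
  the landing direction is rejection-sampled (up to 64 tries) so the
  landing point stays inside a 640 × 480 px viewing field **without
  shrinking the drawn amplitude** — mirror-reflection folding was found
  to bias effective amplitudes (and therefore detected saccade counts)
  downward near the borders. The displacement follows a minimum-jerk
  profile `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`, giving a realistic mid-saccade
  velocity peak (1.875 × amplitude/duration in the continuous limit;
  lower once sampled at 30 Hz, since short saccades span 2–4 samples).

Default class parameters encode the load contrast: class 0 fixates for
0.25 ± 0.08 s with 3 saccades/s of 80 ± 20 px; class 1 fixates for
0.50 ± 0.15 s with 1.5 saccades/s of 50 ± 15 px. These magnitudes are
deliberately well separated: the point of the synthetic study is to
verify the machinery (a pipeline that cannot classify them is broken),
not to estimate realistic effect sizes. Consequently, near-ceiling
accuracies on synthetic data say nothing about accuracy on real drivers;
they say the chain from pixels to significance tests is wired correctly.

The paired **camera channel** is the same trace with i.i.d. Gaussian
position noise (default sd 2 px) and Bernoulli dropout (default 2 %),
dropped samples being flagged invalid rather than removed. The **frame
renderer** draws a bright face disk with two dark pupil disks on a dark
background; the trace position is the midpoint of the pupil centers and
is returned as per-frame ground truth. The renderer emulates geometry
and contrast only — no texture, head pose, occlusion, blinks or lighting
variation — so vision-stage results on synthetic frames bound the
geometric pipeline, not real-video robustness.

## Vision stage

Frames are normalized to [0, 1] (0–255 inputs rescaled). Coordinates are
0-based, origin top-left; ROI boxes are half-open. The face detector is
pluggable; the built-in default takes the largest bright connected
region with a disk-like bounding-box fill (extent ≥ 0.4). Between
detections the ROI is propagated by sparse feature tracking: Shi–Tomasi
corners matched by local normalized cross-correlation (acceptance at
0.6), ROI translated by the median displacement; fewer than 3 confident
matches forces re-detection, as does every 30th frame.

Within the ROI: binarize at 0.5 (strictly-above is foreground), invert,
Sobel gradient magnitude, Otsu threshold on the gradients (a uniform ROI
yields an empty edge map), then a circular Hough transform over the
pupil radius range (default 3–8 px); the two strongest accumulator peaks
become the left/right pupils by ascending x. Frames without a face or
without two circles produce missing trace samples, so the output trace
always has one sample per frame.

## Event segmentation

Speed is the Euclidean displacement over the sample interval; the first
sample and samples adjacent to missing data are undefined. I-VT labeling
(`v ≥ θ` ⇒ saccade) is applied per contiguous block of defined samples;
events never span gaps. The default θ is the Otsu split of the defined
speed distribution — self-calibrating per recording and reproducible — 
with a fixed override available. Minimum-duration rules are applied in a
fixed order: saccade runs shorter than 0.02 s are relabeled fixation and
merged, then fixation runs shorter than 0.1 s are relabeled saccade and
merged. Sample *i* covers (t₍ᵢ₋₁₎, tᵢ], so event durations partition the
defined extent exactly.

## Features and windowing

Windows tile each segment (default 30 s, non-overlapping); events are
clipped at window boundaries, conserving total duration. Standard
deviations use the sample (n−1) convention with sd = 0 for a single
event. Event velocity is summarized by the event's mean sample speed
(peak velocity is retained on the event but not used by the features).
Windows with zero saccades set the seven saccade features to 0; a window
with no events at all is an error. Resampling (for rate changes) is
linear interpolation, with runs of missing data longer than 0.2 s kept
missing.

## Classifiers

Classical models use scikit-learn with the enumerated variants; defaults
are the best-performing settings of the emulated study (linear SVM,
linear LDA, k = 10 euclidean k-NN, Gini tree with max_leaf_nodes = 5,
i.e. ≤ 4 internal splits). The "twoing" tree criterion has no
scikit-learn counterpart and maps to Gini. Features are z-scored with
statistics of the training fold only; folds are stratified; holdout uses
a 0.3 test fraction. Decision scores for ROC are the signed margin (SVM)
or the class-1 probability.

Deep models consume raw (x, y) windows. Normalization centers each
window per channel — absolute screen position carries no class
information — and divides by one dataset-wide per-channel standard
deviation, preserving between-window amplitude differences (per-window
scaling was found to discard most of the class signal). For CPU-scale
training the windows are decimated by linear interpolation, default 120
samples (60 for the LSTM, whose backpropagation-through-time cost grows
with sequence length); the flattened 60 s form at native rate is
2 × 1800 = 3600 values.

* **CNN** (16 layers): input; 3 × (conv–batchnorm–relu–maxpool) with
  16/32/64 filters, kernel 7, pool 2; a 64-unit fully connected layer
  (layer 14, the feature layer for the CNN+SVM hybrid); softmax;
  classification output. Implemented in NumPy with manual
  backpropagation, verified against central finite differences.
* **LSTM** (5 layers): sequence input; a single LSTM layer (forget-gate
  bias 1); fully connected; softmax; output. The last hidden state feeds
  the head.
* **Stacked AE**: two greedily trained single-hidden-layer MLP
  regressions (scikit-learn), 100 then 50 units, each reconstructing its
  input; codes are the ReLU hidden activations. The 50-dim codes feed an
  SVM — Gaussian kernel by default, since a linear margin on the learned
  nonlinear codes was consistently weaker.

Training uses Adam (lr 10⁻³ for the CNN, 10⁻² for the LSTM), batch 32.
Cross-validated deep predictions come from per-fold networks; the model
returned for feature extraction is retrained on all data. Bit
reproducibility is promised for fixed seeds on a fixed platform;
accuracy assertions are tolerance-based.

## Evaluation statistics

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision =
TP/(TP+FP), F1 = harmonic mean of precision and sensitivity, accuracy =
(TP+TN)/total; zero-denominator metrics are flagged NaN rather than
raised. Report tables round half-away-from-zero to two decimals, and F1
is computed from exact (unrounded) precision/recall. ROC curves use the
standard threshold sweep; AUC (trapezoidal) equals the rank-averaged
Mann–Whitney statistic under ties.

The cumulative percentage compares two co-registered channels: per
sample, the percentage absolute difference 100·|ref−test|/ref (reference
in the denominator; zero-reference samples excluded and flagged), an
indicator at a configurable threshold (default 15 %), and
CPᵢ = 100 × (running indicator count)/i. Per-axis curves are averaged
per subject and then across subjects.

The Wilcoxon signed-rank test discards zero differences, mid-ranks ties,
and reports the exact p for small samples (via SciPy's exact path) with
the normal-approximation z always attached; H = 1 iff p < 0.05. The
DeLong test estimates the variance of the paired AUC difference from the
mid-rank structural components (per-positive and per-negative placement
values); a model against itself returns exactly z = 0, p = 1. Which
model pairs to compare is left to the caller; the pipeline reports each
model against the best-AUC model per channel. No multiple-testing
correction is applied.

## Pipeline and reproducibility

`run_experiment` derives one seed per stage as
`blake2s(f"{master_seed}:{stage}") mod 2³¹`, giving independent but
reproducible stage randomness; the manifest records the master seed, the
stage seeds and the full configuration, and `config_from_manifest`
rebuilds the configuration so the classical outputs reproduce byte for
byte. The vision leg is optional and runs on a short subset (default 100
frames) because Hough-based extraction of all ~650 k study frames is out
of proportion for a verification leg; its report is the recovered
fraction and the mean absolute trace error.

## Problem sizes used in the checks

The default test battery uses the full 720-window synthetic study for
the classical models and the scaled-down deep runs (decimated windows,
10–15 epochs), 100 rendered frames for the vision round trip, 200 random
series for the segmentation oracle, and 300 null pairs for the DeLong
calibration. These sizes are the package's own verification choices;
larger runs only sharpen the same comparisons.

## Known limitations

* The synthetic generator fixes class separation by construction;
  synthetic accuracies are machinery checks, not performance estimates
  for real driving data.
* The built-in face detector and renderer assume one bright face on a
  dark background; real video requires binding a pretrained detector.
* The velocity threshold's Otsu default assumes a bimodal speed
  distribution; recordings with very few saccades may need the fixed
  override.
* Smooth pursuit, glissades, microsaccades and blinks are not modeled or
  classified; dispersion-based segmentation is out of scope.
* Gaze is reported in pixel coordinates; no calibration to visual angle
  or scene coordinates is attempted.
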