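# Methods

## The estimation problem

The Apnea-Hypopnea Index (AHI) is the number of scoreable respiratory
events per hour of sleep. Scoring follows the AASM 3 %/arousal rule:
an **apnea** is a nasal-airflow reduction of more than 90 % for at least
10 s; a **hypopnea** is a reduction of more than 30 % for at least 10 s,
and it counts toward the AHI only when it is accompanied by an oxygen
desaturation of at least 3 % starting within 45 s of event onset (type 1)
or by an arousal starting within 5 s after the event ends (type 2). All
other hypopneas (type 3) are excluded. Severity bands: healthy < 5,
mild 5–15, moderate 15–30, severe > 30 events/h. This package treats the
band boundaries as left-closed (an AHI of exactly 15 is moderate); the
clinical phrasing "5–15, 15–30" is ambiguous at the endpoints and a single
convention, tested at 5/15/30 exactly, avoids silent disagreement between
components.

## Pipeline

1. **Preprocessing** (`preprocess`). The first and last 30 min of a night
   are removed as sensor set-up time. Every channel is resampled to a
   common working rate (default 64 Hz) with a natural cubic spline, which
   preserves the higher-frequency content that linear interpolation would
   attenuate. Each channel is then normalised robustly: mean and SD are
   computed from the central 95 % of samples (percentiles 2.5–97.5),
   z-scores are clipped to that band's z-range, and min-max scaling maps
   the result to [0, 1]. The clipping bound makes the min-max step immune
   to isolated artefacts — a single extreme sample moves all other outputs
   by well under 1 % — while constant signals map to 0.5. Normalisation
   runs after resampling by default; both orders are supported and tested,
   since the difference on band-limited signals is below the quantisation
   noise of the recording.
2. **RR intervals** (`preprocess.extract_rri`). R peaks are detected with
   the Pan-Tompkins chain — zero-phase 5–15 Hz band-pass, five-point
   derivative, squaring, 150 ms moving-window integration, adaptive dual
   thresholds with a 200 ms refractory period and RR-based search-back —
   with all constants derived from the working sampling rate rather than
   fixed at the algorithm's original design rate. The RR series is
   converted to a uniformly sampled signal by holding each interval
   between its two beats (step interpolation; a spline variant is
   available by configuration). Zero-phase filtering is used so detected
   peak times can be compared directly against planted ground truth.
3. **SpO₂ delays** (`preprocess.delay_channel`). Oxygen desaturation lags
   the airflow reduction, so delayed copies of SpO₂ (defaults 10, 15, 20,
   25 s) can be appended as extra channels. The shift is a look-ahead:
   the delayed channel at time *t* holds the SpO₂ value at *t + d*, so a
   window anchored at an event onset sees the late oxygen response. The
   trailing *d* seconds hold the signal's final value.
4. **Windowing and labels** (`windows_labels`). Windows are 30 s long with
   a 15 s stride. A window is event-positive when it overlaps an apnea or
   type-1/2 hypopnea by at least 1 s (the minimal rule consistent with
   binary window labels; the threshold is configurable and its
   sensitivity is test-covered), and sleep-positive when at least half of
   it lies in sleep-staged epochs. Training sets are balanced by
   downsampling normal windows to the positive count.
5. **Models** (`models`). Each channel has its own 1-D CNN with the
   EfficientNetV2 stage structure: fused-MBConv blocks early, MBConv with
   squeeze-excitation late, kernel size 3 throughout, the 2-D stride
   schedule applied along time, global average pooling, and a 2-logit
   head. The `full` profile mirrors the V2-S widths and pools to 1280
   features; `small` (256) and `tiny` (64) shrink depth and width but keep
   the stage structure so behaviour scales down faithfully. Training uses
   Adam on categorical cross-entropy with early stopping: when the
   validation loss has not decreased for 8 consecutive epochs, training
   stops and the best-validation weights are restored. Features are taken
   at the last global pooling (`last_gap`) or at the stage preceding the
   1×1 head convolution (`third_last`), pooled to fixed width. The
   network and its training loop are implemented directly on numpy
   (`driven.nn`) with explicit backward passes; training is therefore
   bit-reproducible given a seed. Concatenated per-channel features feed
   a LightGBM classifier whose hyperparameters come from a seeded random
   search (num_leaves 7–63, log-uniform learning rate 0.02–0.3,
   min_child_samples 5–50, feature_fraction 0.5–1, n_estimators 50–300),
   selected by validation AUPRC. The sleep/awake model is the same
   architecture trained on sleep labels; only the label column differs.
6. **Calibration and estimation** (`calibrate_estimate`). The event
   threshold is the probability at which precision equals recall on
   validation windows (scanning all distinct scores plus {0, 1};
   ties resolve toward higher precision, then toward the higher
   threshold). The sleep threshold is fixed at 0.5. Each sleep-classified
   15 s step contributes 15 s to total sleep time; the paper-style
   estimator is the positive-window ratio (positive sleep windows over
   all sleep windows) mapped through a linear regression fitted on
   calibration patients with per-patient weight 1/(severity-class count).
   Predictions are clipped at zero — the regression can extrapolate
   negative for near-empty nights. Nights are rendered as an
   awake/normal/event timeline; consecutive event steps merge into
   [first anchor, last anchor + 30 s) intervals, which deliberately
   reproduces the smoothing behaviour of the windowed detector: bursts of
   short events closer than one window length appear as a single merged
   interval.

## Synthetic data

`synthetic_psg` generates nights with exactly known ground truth. Sleep is
laid out as contiguous blocks (onset and offset wakefulness plus mid-night
awakenings) to exercise sleep-time estimation. Events are planted only
inside sleep, separated by at least 10 s of normal breathing; after an
apnea or type-1 hypopnea the gap is stretched so the delayed desaturation
starts before the next event, keeping the subtype rules unambiguous.
Placement allocates events to sleep runs proportionally to run length and
distributes the remaining slack by exponential stick-breaking, so event
density is smooth in the target AHI rather than clustered.

Waveforms are deliberately minimal fixtures: respiratory effort and
airflow are amplitude-modulated 0.25 Hz sinusoids with Gaussian noise
(airflow envelope 0.02 of baseline during apneas, 0.40 during hypopneas;
effort 0.30/0.55); SpO₂ is a 97 % baseline with piecewise-exponential
desaturations of depth ≥ 3 % starting a configurable delay (default 15 s)
after apnea/type-1 onsets; the ECG is a train of Gaussian R-wave templates
at exactly known beat times; awake periods show large erratic effort with
extra broadband noise. Cohorts draw per-patient target AHIs uniformly
within each severity band, with a 0.5 events/h margin from the band edges
because a patient planted exactly on a boundary has no well-defined true
class. Defaults describe a realistic study night: 8 h in bed,
sleep fraction 0.875, event durations 10–25 s.

What passing tests on this generator do and do not show: they verify the
scoring rules, the window/label bookkeeping, the calibration algebra, and
that the learned pipeline can recover planted structure from clean
amplitude cues. They do not show performance on real polysomnography,
where event morphology, artefacts, inter-patient variability and
sensor-specific behaviour are far richer than these fixtures.

## Problem sizes and numerical choices

- The oracle-path cohort (ground-truth labels substituted for model
  outputs) uses 60 patients × 8 h nights at reduced sampling rates, since
  only the annotations enter that computation.
- The learned-path study uses 60 patients (40 for training and
  calibration, 20 held out) × 1.5 h nights at an 8 Hz working rate with
  the `tiny` profile and two channels (abdominal + SpO₂). These are the
  smallest sizes at which the window statistics and the four-class
  severity evaluation are meaningful; they are the package's desk-scale
  study conditions, not a claim about clinical-scale training.
- Metric conventions: AUROC is the Mann-Whitney rank statistic with ties
  counted half; AUPRC uses step-wise integration (no linear interpolation
  between operating points, which is optimistic). Ratios with zero
  denominators are reported as 0 with an `undefined` flag. The macro
  F1 over severity classes averages the classes present in truth or
  prediction, so absent classes do not deflate perfect agreement.
- EDF files use 16-bit samples in 1 s records; physical scaling bounds are
  written at the densest precision that fits the 8-character header
  fields, keeping write/read round trips within one quantisation step.
- All randomness — simulation, splits, balancing, initialisation,
  dropout, hyperparameter search — flows from explicit integer seeds.

## Known limitations

- The generator makes no attempt at physiological realism: no
  cardiorespiratory coupling, no central-vs-obstructive morphology, no
  motion artefacts, no sensor-specific SpO₂ averaging.
- Hypopnea subtype recovery from foreign annotation files depends on the
  desaturation/arousal context recorded in the same file.
- The ratio-regression estimator saturates for extremely dense event
  bursts (windows merge), which can underestimate severe AHI — inherent
  to the 30 s windowing and visible in the night segmentation.
- EDF support covers the plain 16-bit format with 1 s records; EDF+
  annotations, BDF and vendor formats are out of scope.
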