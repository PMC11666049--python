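# Methods

This note documents the models, conventions and numerical choices behind
spindlebox, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic data does and does not show.

## Problem framing

Sleep spindles and K-complexes are scored by experts who look at the EEG
trace. spindlebox frames that visual inspection as object detection: a
record is cut into 5-second windows, each window is rendered as an image of
the waveform, and every annotated event interval becomes an axis-aligned
pixel bounding box. A detector (learned or not) proposes boxes with
confidence scores, and performance is summarised by average precision over a
2-class × 3-IoU-threshold grid.

## Data model and units

A record is a single uniformly sampled channel; amplitudes are microvolts
internally, converted at ingress (EDF data is read through `mne`, which
yields volts; the EDF writer declares `uV` physical dimension). Annotations
are `(class, onset, duration)` in seconds relative to the record start — the
convention of sleep-scoring annotation files — never wall-clock time. When
two scorers annotated the same record, both are kept, tagged by scorer;
reconciliation is an explicit caller choice (`merge_scorers`, union by
default, intersection available) because no single convention is canonical.

EDF encodes samples as 16-bit integers against a declared physical range, so
a write→read round trip is exact only up to the quantisation step
`(phys_max − phys_min)/65535`; the writer picks the tightest symmetric range
that covers the data, and tests assert the round-trip error against exactly
that step. Pascal VOC label export converts the package's 0-based half-open
boxes to VOC's 1-based inclusive corners (`xmin = x_min + 1`,
`xmax = x_min + width`); the ±1 arithmetic can perturb float coordinates by
one ulp, so VOC round trips are checked to 1e-9 while CSV and COCO round
trips are bit-exact.

## Synthetic sleep EEG

The simulator exists so every downstream stage can be exercised with exact
ground truth. It emulates three ingredients:

* **Background**: stationary AR(2) noise (coefficients 1.2, −0.36 — a
  red-shifted, pink-ish spectrum) scaled to 15 μV RMS by default. Real sleep
  EEG is non-stationary and contains artifacts; a stationary background is a
  deliberate simplification that makes the signal-to-noise ratio of planted
  events controllable and the detector's operating point interpretable.
* **Spindles**: a sinusoid drawn uniformly from 11–16 Hz under a raised-
  cosine (Hann) envelope — smooth onset/offset as in real spindles — with
  duration uniform in [0.5, 2.0] s and peak amplitude uniform in [25, 50] μV
  (never above the 50 μV definitional ceiling).
* **K-complexes**: three half-cosine lobes of widths 200/550/900 ms with
  relative extremum amplitudes (+0.4, −1.0, +0.5) of a 75 μV scale. The
  phase durations follow the standard morphological definition; the lobe
  amplitude ratios are free parameters chosen to give the characteristic
  sharp negative deflection.

Event counts are Poisson (defaults: 3 spindles and 1.5 K-complexes per
minute, a realistic N2 density); onsets are drawn uniformly and rejection-
sampled against a 1 s minimum gap, with a bounded retry budget so impossible
densities fail loudly rather than loop. All randomness flows through one
`numpy` Generator, so a seed fixes the record bit-for-bit.

What passing tests on this data do **not** show: robustness to artifacts,
non-stationarity, reference-scheme differences, or scorer disagreement in
real recordings. The simulator validates the pipeline's mechanics and the
evaluation arithmetic, not clinical performance.

## Rendering geometry

Each window is rasterised by drawing a polyline through one vertex per
sample — the native sampling interval (5 ms at 200 Hz, 3.90625 ms at
256 Hz), with no resampling. The canvas defaults to 800×400 px, comfortably
larger than the ±30 px translation range of the augmentations; time and
amplitude map affinely onto the drawable area (top-left origin, amplitude
increasing upward). The amplitude range is fixed (±120 μV by default) rather
than per-window autoscaled, so amplitude semantics are comparable across
windows; per-window autoscale is available but not default.

"5-second non-overlapping views" are implemented as tumbling windows (stride
= window length), the only self-consistent reading. Events crossing a window
boundary are assigned to the window holding the majority of their duration
(ties to the earlier window) and clipped to it; an `onset` policy is also
provided. A box's x-extent is the affine image of the event interval; its
y-extent is the pixel span of the event's own min/max sample values expanded
by 5% of the canvas height per side (which also absorbs the stroke width),
clipped to the canvas. Rendering uses Pillow's polyline rasteriser: it is
deterministic, and its lack of antialiasing makes the "every trace pixel of
the event lies inside its box" invariant directly checkable by raster scan.

## Augmentation

Geometric augmentation scales about the canvas origin and translates on a
fixed canvas (content resampled bilinearly, background-filled); box corners
go through the same affine `x′ = s_x·x + t_x`. Colour augmentation adds
offsets in HSV space on [0, 1]-normalised channels: hue wraps modulo 1,
saturation and value clip. A draw that pushes any box outside the canvas is
redone, up to 25 retries, after which the input is passed through unchanged
with a warning — keeping dataset size stable rather than erroring. Identity
parameters are an exact fixed point of the geometric path and a ≤1-intensity-
level fixed point of the HSV round trip.

## Evaluation protocol

Matching is greedy in descending confidence: each detection takes the
unmatched same-class ground truth in its image with the highest IoU, if that
IoU ≥ threshold (non-strict, as in common tooling); each truth matches at
most once. Precision/recall accumulate over the pooled detections of the
whole image set. AP integrates the monotone precision envelope over recall
(`all_points`, the default); a COCO-style 101-point sample is available and
surfaced in the report, since the protocol's {0.5, 0.6, 0.7} threshold grid
is not COCO's. mAP is the unweighted mean of the AP cells. Cross-validation
aggregation reports the fold mean and the **population** (divisor-N)
standard deviation — the form that reproduces the published fold tables;
percentages are rounded half-away-from-zero to one decimal for reporting.

Splits: fraction splits use largest-remainder rounding so the partition is
exact; k-fold uses near-equal shuffled folds; leave-subject-out holds out
every item of one subject per fold.

## Baseline detector

The non-learned baseline closes the loop at desk scale. Spindles: zero-phase
(forward–backward) 4th-order Butterworth band-pass at 11–16 Hz, 0.25 s
moving-RMS envelope, dual-threshold rule — candidates must exceed 2.5× the
background level (median envelope) and are extended outward to the 1.5×
crossing, keeping runs ≥ 0.5 s. The dual threshold is standard practice in
envelope-based spindle detectors; with a single threshold the reported
interval hugs the envelope peak and under-covers the true extent.
K-complexes: normalised cross-correlation against the canonical three-lobe
template, peaks above 0.6 correlation, non-maximum suppression over one
template length. Detected intervals are converted to image-space boxes
through the *same* window-assignment and box-geometry code path as ground
truth, so a perfect interval yields the identical box. At the default
simulator SNR the baseline's false-alarm rate on event-free background is
~0.2 spindles/min (median 0 across seeds).

## Pipeline and reproducibility

The `run` driver executes simulate → render → detect → evaluate under one
run directory with the resolved config; the single global seed fans out to
per-stage child seeds via `numpy.random.SeedSequence`, so stages are
individually reproducible and a fixed config yields a byte-identical report.
Config files are schema-checked with unknown keys rejected by name.

The training harness is an adapter, not a trainer: it logs hyperparameters
(SGDM, lr 0.001, batch 2, L2 1e-4, momentum 0.9, ≤30 epochs) verbatim,
raises a distinct capability error when no detector backend is installed,
and ships an explicitly non-learned "oracle" backend (echoes ground truth)
purely to smoke-test the dataset → detections → evaluation plumbing.

## Problem sizes

Tests and the acceptance script use desk-scale sizes chosen to exercise
every code path with stable statistics: 1–10 minute simulated records,
1000-burst simulator sweeps, 10,000 augmentation draws, 100 PR instances
against a 10⁻⁶-resolution integration oracle, and 500 random matching
layouts against a brute-force oracle.

## Known limitations

* The simulator's background is stationary and artifact-free; detector
  scores on it are upper bounds relative to real recordings.
* Published cross-validation cells can be re-aggregated only to the
  precision their printed rounding supports: means reproduce exactly, and
  the one-decimal rounding of the inputs bounds recomputed SDs to within one
  final-digit unit (5 of 6 cells reproduce exactly).
* Ground-truth box height has no canonical definition; the event-amplitude-
  span-plus-5% rule is this package's choice, configurable via `pad_frac`.
* Multi-channel montages, re-referencing, resampling and sleep staging are
  out of scope.
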