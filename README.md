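# spindlebox

Detection and localisation of **sleep spindles** and **K-complexes** in EEG,
treated as an *object-detection* problem on rendered waveform images.

Sleep spindles (11–16 Hz bursts, amplitude below ~50 μV, lasting ≥ 0.5 s) and
K-complexes (a ~200 ms positive ascent, ~550 ms negative descent, and a
prolonged ~900 ms positive peak) are the two hallmark NREM-stage-N2 events
that sleep scorers locate by visually inspecting the EEG trace. This package
implements the data-engineering and evaluation machinery needed to train and
score detectors that inspect the waveform the same way:

* **signal I/O** — single-channel EEG records (EDF) and event annotation
  tables (`class,onset,duration[,scorer]` CSV, or DREAMS-style two-column
  text), with a union/intersection option for reconciling multiple scorers;
* **simulation** — synthetic sleep EEG with planted, exactly annotated
  spindles and K-complexes on AR(2) background noise, so the entire pipeline
  is testable at desk scale with no dataset downloads;
* **rendering** — 5-second tumbling windows rasterised at the native sampling
  interval (one plotted point per sample: 5 ms at 200 Hz, 3.90625 ms at
  256 Hz; no resampling), with each annotated interval converted to a pixel
  bounding box; export to COCO JSON, Pascal VOC XML, or flat CSV, plus
  class-balancing by undersampling or augmentation;
* **augmentation** — random x/y scaling in [0.9, 1.1], translation in
  [−30, 30] px, and hue/saturation/brightness shifts in [−0.2, 0.2], with
  boxes carried through the same affine map and invalid draws redone;
* **evaluation** — the AP/mAP protocol: greedy IoU matching, pooled
  precision–recall curves, average precision as the area under the PR curve,
  and

  &nbsp;&nbsp;mAP = (1/6) Σ<sub>j∈{0.5,0.6,0.7}</sub> Σ<sub>i∈{SS,KC}</sub> AP<sub>ij</sub>,

  plus fraction / k-fold / leave-subject-out splits and fold aggregation
  (mean and population SD);
* **a non-learned baseline detector** — sigma-band envelope thresholding for
  spindles and normalised template cross-correlation for K-complexes — so
  `simulate → render → detect → evaluate` runs end to end on one CPU.

Deep detector backbones (Faster R-CNN / YOLO families) are deliberately *not*
re-implemented; a thin training harness hands exported datasets to an
external backend when one is installed.

## Worked example

Run the full pipeline on 5 minutes of simulated EEG:

```sh
spindlebox run --seed 5 --duration 300 --out runs/demo
```

prints the evaluation of the baseline detector against the simulator's
ground truth:

```
  IoU  class       AP %  (TP/FP/FN)
  50%  spindle    100.0  (21/0/0)
  60%  spindle    100.0  (21/0/0)
  70%  spindle     66.8  (16/5/5)
  50%  kcomplex   100.0  (8/0/0)
  60%  kcomplex   100.0  (8/0/0)
  70%  kcomplex   100.0  (8/0/0)
mAP = 94.5%
```

Each row is one cell of the 2-class × 3-IoU-threshold grid: at IoU ≥ 50% the
baseline recovers all 21 planted spindles and 8 K-complexes in this record
with no false alarms; at the stricter 70% overlap requirement some spindle
boxes no longer align tightly enough, so true positives drop to 16 and AP
falls — the same threshold sensitivity detector studies report. The run
directory contains the rendered dataset (`dataset/images/*.png`,
`dataset/labels.json`), the detections, the evaluation report and the
resolved configuration.

The same stages are available individually (`spindlebox simulate`, `render`,
`augment`, `split`, `detect-baseline`, `train`, `evaluate`) and as library
functions (`spindlebox.simulate_record`, `render_dataset`,
`evaluate_detections`, ...).

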