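"""Non-learned reference detectors for spindles and K-complexes.

These operate in the signal domain and exist so the full pipeline —
simulate → render → detect → evaluate — runs end to end on one CPU:

* **Spindles**: zero-phase band-pass in the sigma band (11–16 Hz), moving-RMS
  envelope, threshold at a multiple of the background RMS, keep threshold
  crossings lasting at least the 0.5 s minimum spindle duration.  The
  detection score is the peak envelope inside the run, normalized to [0, 1].
* **K-complexes**: normalized cross-correlation against the canonical
  three-lobe template, peak-picking above a correlation threshold with
  non-maximum suppression over one template length.  The score is the
  correlation coefficient.

Detected time intervals are converted to image-space detections through the
exact same window-assignment and box-geometry path as the ground truth, so
detector and truth boxes are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .render import (
    PlotGeometry,
    interval_to_bbox,
    segment_record,
    DegenerateBoxError,
)
from .evaluate import Detection
from .signal_io import EEGRecord, EventAnnotation, EventClass
from .simulate import kcomplex_waveform

__all__ = [
    "BaselineParams",
    "detect_spindles",
    "detect_kcomplexes",
    "intervals_to_detections",
    "detect_events",
]


@dataclass(frozen=True)
class BaselineParams:
    """Tunables of the baseline detectors.

    The spindle band and minimum duration restate the event definition
    (11–16 Hz, ≥ 0.5 s); the RMS multiple and correlation threshold set the
    operating point on synthetic data.
    """

    spindle_band: tuple[float, float] = (11.0, 16.0)
    envelope_window_s: float = 0.25
    spindle_threshold_rms: float = 2.5
    spindle_extent_rms: float = 1.5
    min_duration_s: float = 0.5
    kc_phase_ms: tuple[float, float, float] = (200.0, 550.0, 900.0)
    correlation_threshold: float = 0.6

    def __post_init__(self) -> None:
        lo, hi = self.spindle_band
        if not 0 < lo < hi:
            raise ValueError(f"spindle band must satisfy 0 < lo < hi, got {self.spindle_band}")
        if self.spindle_threshold_rms <= 0 or self.correlation_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (0, 1)")


def _bandpass(samples: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (no onset bias)."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, samples)


def _moving_rms(x: np.ndarray, n: int) -> np.ndarray:
    n = max(int(n), 1)
    kernel = np.ones(n) / n
    return np.sqrt(np.convolve(x**2, kernel, mode="same"))


def detect_spindles(
    record: EEGRecord, params: BaselineParams = BaselineParams()
) -> list[tuple[float, float, float]]:
    """Detect spindle intervals; returns (onset s, duration s, score) tuples.

    Dual-threshold (hysteresis) rule, as is standard for envelope-based
    spindle detectors: a candidate starts where the envelope exceeds
    ``spindle_threshold_rms`` × background and its extent is then grown
    outward to where the envelope falls back below ``spindle_extent_rms`` ×
    background, so the reported interval covers the whole burst rather than
    only its peak.  The background level is the median of the band-passed
    envelope (robust to the events themselves).
    """
    lo, hi = params.spindle_band
    if record.fs <= 2 * hi:
        raise ValueError(
            f"sampling rate {record.fs} Hz cannot resolve the {hi} Hz band edge"
        )
    filtered = _bandpass(record.samples, record.fs, params.spindle_band)
    env = _moving_rms(filtered, int(params.envelope_window_s * record.fs))
    background = float(np.median(env))
    if background <= 0:
        return []
    t_high = params.spindle_threshold_rms * background
    t_low = min(params.spindle_extent_rms * background, t_high)
    n = env.size

    def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
        d = np.diff(mask.astype(np.int8), prepend=0, append=0)
        return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))

    low_runs = _runs(env >= t_low)
    out = []
    min_len = int(params.min_duration_s * record.fs)
    peak_cap = max(float(env.max()), t_high)
    for i0, i1 in low_runs:
        peak = float(env[i0:i1].max())
        if peak < t_high or i1 - i0 < min_len:
            continue
        # map [t_high, global peak] → (0, 1], preserving envelope order
        score = (
            1.0
            if peak_cap == t_high
            else (peak - t_high) / (peak_cap - t_high)
        )
        score = float(np.clip(0.05 + 0.95 * score, 0.0, 1.0))
        out.append((i0 / record.fs, (i1 - i0) / record.fs, score))
    return out


def detect_kcomplexes(
    record: EEGRecord, params: BaselineParams = BaselineParams()
) -> list[tuple[float, float, float]]:
    """Detect K-complex intervals by normalized template cross-correlation.

    Returns (onset s, duration s, score) with duration equal to the template
    length; overlapping peaks are suppressed within one template length.
    """
    template = kcomplex_waveform(record.fs, params.kc_phase_ms, amp=1.0)
    m = template.size
    if record.n_samples < m:
        raise ValueError(
            f"record of {record.n_samples} samples is shorter than the "
            f"{m}-sample template"
        )
    x = record.samples
    t0 = template - template.mean()
    t_norm = float(np.sqrt(np.sum(t0**2)))
    # sliding dot product and sliding window norms
    corr = np.correlate(x, t0, mode="valid")
    ones = np.ones(m)
    s1 = np.convolve(x, ones, mode="valid")
    s2 = np.convolve(x**2, ones, mode="valid")
    var = np.maximum(s2 - s1**2 / m, 1e-12)
    ncc = corr / (t_norm * np.sqrt(var))
    peaks, props = sps.find_peaks(ncc, height=params.correlation_threshold, distance=m)
    out = []
    for p, h in zip(peaks, props["peak_heights"]):
        out.append((p / record.fs, m / record.fs, float(np.clip(h, 0.0, 1.0))))
    return out


def intervals_to_detections(
    intervals: list[tuple[float, float, float]],
    event_class: EventClass,
    record: EEGRecord,
    geometry: PlotGeometry,
    window_s: float = 5.0,
    pad_frac: float = 0.05,
    assign_policy: str = "majority",
    image_ids: dict[int, object] | None = None,
) -> list[Detection]:
    """Map detected time intervals to image-space detections.

    Each interval is turned into an annotation-shaped object and pushed
    through the same :func:`~spindlebox.render.segment_record` assignment and
    :func:`~spindlebox.render.interval_to_bbox` geometry as the ground truth,
    so a detection whose interval equals a truth annotation produces the
    identical box.  ``image_ids`` optionally maps window index → image id
    (defaults to the window index itself).
    """
    if abs(geometry.window_s - window_s) > 1e-9:
        raise ValueError(
            f"geometry window {geometry.window_s} s does not match window_s={window_s}"
        )
    pseudo = []
    scores: dict[tuple[float, float], float] = {}
    for onset, duration, score in intervals:
        onset = max(0.0, min(onset, record.duration_s - 1e-9))
        duration = min(duration, record.duration_s - onset)
        if duration <= 0:
            continue
        ann = EventAnnotation(event_class, onset, duration)
        pseudo.append((ann, score))

    detections: list[Detection] = []
    # reuse the shared segmentation path one annotation at a time so each
    # detection keeps its own confidence
    for ann, score in pseudo:
        windows = segment_record(record, [ann], window_s, assign_policy)
        for w, (samples, anns) in enumerate(windows):
            for rel in anns:
                try:
                    box = interval_to_bbox(rel, samples, record.fs, geometry, pad_frac)
                except DegenerateBoxError:
                    continue
                image_id = image_ids[w] if image_ids is not None else w
                detections.append(Detection(box, event_class, score, image_id))
    return detections


def detect_events(
    record: EEGRecord,
    geometry: PlotGeometry,
    params: BaselineParams = BaselineParams(),
    window_s: float = 5.0,
    pad_frac: float = 0.05,
    image_ids: dict[int, object] | None = None,
) -> list[Detection]:
    """Run both baseline detectors and return image-space detections."""
    out = intervals_to_detections(
        detect_spindles(record, params),
        EventClass.SPINDLE,
        record,
        geometry,
        window_s,
        pad_frac,
        image_ids=image_ids,
    )
    out += intervals_to_detections(
        detect_kcomplexes(record, params),
        EventClass.KCOMPLEX,
        record,
        geometry,
        window_s,
        pad_frac,
        image_ids=image_ids,
    )
    return out
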