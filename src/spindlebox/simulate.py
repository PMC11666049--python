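"""Synthetic sleep-EEG generation with planted, annotated events.

The simulator emulates the two NREM-N2 event types the detectors target:

* **Sleep spindles** — bursts of 11–16 Hz oscillation, amplitude kept below
  50 μV, lasting at least 0.5 s.  Generated as a sinusoid under a raised-cosine
  (Hann) envelope so onset and offset are smooth, as real spindles are.
* **K-complexes** — large biphasic transients: a ~200 ms positive ascent, a
  ~550 ms negative descent, then a prolonged ~900 ms positive peak.  Generated
  as three half-cosine lobes with relative extremum amplitudes
  (+0.4, −1.0, +0.5) of the configured peak amplitude.

Background activity is stationary AR(2) noise scaled to a configurable RMS
(default 15 μV) — a controllable, pink-ish stand-in for real sleep EEG that
gives a well-defined signal-to-noise ratio for the planted events.  Events are
placed by rejection sampling of uniform onsets subject to a minimum gap, and
each planted event is returned with an exact ground-truth annotation, so every
downstream stage (rendering, augmentation, detection, evaluation) can be
exercised without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import EEGRecord, EventAnnotation, EventClass

__all__ = [
    "SimulationConfig",
    "spindle_waveform",
    "kcomplex_waveform",
    "background_noise",
    "simulate_record",
]

#: spindle definition bounds used for validation
MIN_SPINDLE_DURATION_S = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated sleep-EEG record.

    Defaults follow the standard quantitative definitions of the two events:
    spindles at 11–16 Hz, below 50 μV, at least 0.5 s; K-complex phase
    durations of 200/550/900 ms.  Event rates default to values that give a
    realistic NREM-N2 density (a few spindles and about one K-complex per
    minute).
    """

    duration_s: float = 1800.0
    fs: float = 200.0
    seed: int = 0
    spindle_rate_per_min: float = 3.0
    kcomplex_rate_per_min: float = 1.5
    spindle_freq_range: tuple[float, float] = (11.0, 16.0)
    spindle_duration_range: tuple[float, float] = (0.5, 2.0)
    spindle_amp_max: float = 50.0
    kc_phase_ms: tuple[float, float, float] = (200.0, 550.0, 900.0)
    kc_amp: float = 75.0
    background_rms: float = 15.0
    ar_coeffs: tuple[float, ...] = (1.2, -0.36)
    min_gap_s: float = 1.0
    subject_id: str = "sim-0"
    channel: str = "C3-sim"

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if self.spindle_rate_per_min < 0 or self.kcomplex_rate_per_min < 0:
            raise ValueError("event rates must be >= 0")
        lo, hi = self.spindle_freq_range
        if not (0 < lo <= hi < self.fs / 2):
            raise ValueError(
                f"spindle frequency range {self.spindle_freq_range} must lie "
                f"inside (0, fs/2) = (0, {self.fs / 2})"
            )
        if any(p <= 0 for p in self.kc_phase_ms):
            raise ValueError("K-complex phase durations must be positive")
        if self.min_gap_s < 0:
            raise ValueError("min_gap_s must be >= 0")
        dlo, dhi = self.spindle_duration_range
        if dlo < MIN_SPINDLE_DURATION_S or dhi < dlo:
            raise ValueError(
                "spindle_duration_range must be well-ordered with lower bound "
                f">= {MIN_SPINDLE_DURATION_S} s"
            )


def spindle_waveform(
    freq: float, duration: float, amplitude: float, fs: float
) -> np.ndarray:
    """A sleep-spindle burst: sinusoid under a raised-cosine envelope.

    The envelope is a Hann window, so the first and last samples are ~0 and
    the peak absolute amplitude never exceeds *amplitude* (in μV).

    Raises
    ------
    ValueError
        If *duration* is below 0.5 s (shorter bursts do not qualify as
        spindles) or *freq* is not resolvable at *fs*.
    """
    if duration < MIN_SPINDLE_DURATION_S:
        raise ValueError(
            f"spindle duration must be >= {MIN_SPINDLE_DURATION_S} s, got {duration}"
        )
    if not (0 < freq < fs / 2):
        raise ValueError(f"frequency {freq} Hz not in (0, fs/2) for fs={fs}")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / duration))
    return amplitude * envelope * np.sin(2.0 * np.pi * freq * t)


def kcomplex_waveform(
    fs: float,
    phase_ms: tuple[float, float, float] = (200.0, 550.0, 900.0),
    amp: float = 75.0,
    lobe_gains: tuple[float, float, float] = (0.4, -1.0, 0.5),
) -> np.ndarray:
    """A K-complex template: three half-cosine lobes with (+, −, +) polarity.

    Phase widths are in milliseconds — by default the canonical 200 ms
    positive ascent, 550 ms negative descent, 900 ms positive peak — and the
    lobe extrema are *lobe_gains* × *amp* μV.  Total length is
    ``round(sum(phase_ms)/1000 * fs)`` samples.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if len(phase_ms) != 3 or any(p <= 0 for p in phase_ms):
        raise ValueError(f"phase_ms must be three positive durations, got {phase_ms}")
    total_s = sum(phase_ms) / 1000.0
    n_total = int(round(total_s * fs))
    # lobe boundaries in samples, chosen so the lobes tile n_total exactly
    edges = np.round(np.cumsum([0.0, *phase_ms]) / 1000.0 * fs).astype(int)
    edges[-1] = n_total
    out = np.zeros(n_total)
    for gain, a, b in zip(lobe_gains, edges[:-1], edges[1:]):
        m = b - a
        if m <= 0:
            continue
        # half-cosine arc: 0 at the lobe edges, |gain*amp| at the centre
        x = (np.arange(m) + 0.5) / m
        out[a:b] = gain * amp * np.sin(np.pi * x)
    return out


def background_noise(
    n: int, rms: float, ar_coeffs: tuple[float, ...], rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR noise scaled to the requested RMS (μV)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rms == 0:
        return np.zeros(n)
    coeffs = np.asarray(ar_coeffs, dtype=float)
    burn = 200
    white = rng.standard_normal(n + burn)
    x = np.empty(n + burn)
    p = coeffs.size
    x[:p] = white[:p]
    for i in range(p, n + burn):
        x[i] = coeffs @ x[i - p : i][::-1] + white[i]
    x = x[burn:]
    x = x - x.mean()
    return x * (rms / np.sqrt(np.mean(x**2)))


def _place_events(
    rng: np.random.Generator,
    n_events: int,
    durations: np.ndarray,
    total_s: float,
    min_gap_s: float,
    max_retries: int = 1000,
) -> np.ndarray:
    """Uniform onsets under a minimum-gap constraint, by rejection sampling."""
    onsets: list[float] = []
    placed: list[tuple[float, float]] = []  # (onset, offset) pairs
    for dur in durations:
        ok = False
        for _ in range(max_retries):
            onset = rng.uniform(0.0, total_s - dur)
            if all(
                onset >= off + min_gap_s or onset + dur + min_gap_s <= on
                for on, off in placed
            ):
                placed.append((onset, onset + dur))
                onsets.append(onset)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {n_events} events of total duration "
                f"{durations.sum():.1f} s with gap {min_gap_s} s in {total_s} s "
                f"after {max_retries} retries; lower the event rates"
            )
    return np.asarray(onsets)


def simulate_record(
    config: SimulationConfig,
) -> tuple[EEGRecord, list[EventAnnotation]]:
    """Generate a synthetic EEG record plus exact ground-truth annotations.

    Event counts are Poisson with mean ``rate × duration``; identical seeds
    produce bit-identical output.  Returned annotations are sorted by onset
    and never overlap (separated by at least ``min_gap_s``).
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    samples = background_noise(n, config.background_rms, config.ar_coeffs, rng)

    n_sp = rng.poisson(config.spindle_rate_per_min * config.duration_s / 60.0)
    n_kc = rng.poisson(config.kcomplex_rate_per_min * config.duration_s / 60.0)

    kc_dur_s = sum(config.kc_phase_ms) / 1000.0
    sp_durs = rng.uniform(*config.spindle_duration_range, size=n_sp)
    durations = np.concatenate([sp_durs, np.full(n_kc, kc_dur_s)])
    classes = [EventClass.SPINDLE] * n_sp + [EventClass.KCOMPLEX] * n_kc

    annotations: list[EventAnnotation] = []
    if durations.size:
        onsets = _place_events(
            rng, durations.size, durations, config.duration_s, config.min_gap_s
        )
        for cls, onset, dur in zip(classes, onsets, durations):
            start = int(round(onset * config.fs))
            if cls is EventClass.SPINDLE:
                freq = rng.uniform(*config.spindle_freq_range)
                # headroom below the 50 μV ceiling, as real spindles vary
                amp = rng.uniform(0.5, 1.0) * config.spindle_amp_max
                wave = spindle_waveform(freq, dur, amp, config.fs)
            else:
                wave = kcomplex_waveform(config.fs, config.kc_phase_ms, config.kc_amp)
            stop = min(start + wave.size, n)
            samples[start:stop] += wave[: stop - start]
            annotations.append(EventAnnotation(cls, onset, dur))

    annotations.sort(key=lambda a: a.onset)
    record = EEGRecord(
        samples=samples,
        fs=config.fs,
        channel=config.channel,
        subject_id=config.subject_id,
    )
    return record, annotations
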