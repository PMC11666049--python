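"""EEG record and event-annotation I/O.

The in-memory model is a single-channel, uniformly sampled voltage series in
microvolts (:class:`EEGRecord`) plus ground-truth event intervals
(:class:`EventAnnotation`) expressed in seconds relative to the start of the
record, the same (onset, duration) convention sleep-scoring annotation files
use.

Signals travel as EDF (European Data Format).  Reading goes through ``mne``;
writing is done by a small built-in EDF writer (16-bit integer encoding, one
data record per second) because amplitudes are quantized by the format, the
write→read round trip is exact only up to the quantization step implied by the
written physical range — see :func:`edf_quantization_step`.

Annotation tables are plain text: either a CSV with header
``class,onset,duration[,scorer]`` or the two-column whitespace-separated
``onset duration`` layout used by the DREAMS distribution (event class given
by the caller).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EventClass",
    "EEGRecord",
    "EventAnnotation",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "merge_scorers",
    "edf_quantization_step",
]


class EventClass(str, enum.Enum):
    """The two NREM-sleep event types the pipeline detects."""

    SPINDLE = "spindle"
    KCOMPLEX = "kcomplex"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_event_class(value: "EventClass | str") -> EventClass:
    if isinstance(value, EventClass):
        return value
    try:
        return EventClass(str(value).strip().lower())
    except ValueError:
        raise ValueError(
            f"unknown event class {value!r}; expected one of "
            f"{[c.value for c in EventClass]}"
        ) from None


@dataclass(frozen=True)
class EEGRecord:
    """A uniformly sampled single-channel EEG voltage series.

    Parameters
    ----------
    samples:
        Amplitudes in microvolts (μV), one value per sample.
    fs:
        Sampling rate in Hz; must be positive.
    channel:
        Channel label (e.g. ``"C3"``).
    subject_id:
        Identity of the recorded subject; used by leave-subject-out splits.
    start_time:
        Offset of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    channel: str = "EEG"
    subject_id: str = "S0"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds from record start."""
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class EventAnnotation:
    """A ground-truth event interval: (class, onset s, duration s)."""

    event_class: EventClass
    onset: float
    duration: float
    scorer: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_class", _as_event_class(self.event_class))
        object.__setattr__(self, "onset", float(self.onset))
        object.__setattr__(self, "duration", float(self.duration))
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def offset(self) -> float:
        """End of the interval in seconds from record start."""
        return self.onset + self.duration

    def validate_against(self, record: EEGRecord) -> None:
        """Raise if the interval does not fit inside *record*."""
        if self.offset > record.duration_s + 1e-9:
            raise ValueError(
                f"annotation [{self.onset}, {self.offset}) s extends past the "
                f"record duration {record.duration_s} s"
            )


# ---------------------------------------------------------------------------
# EDF signal I/O
# ---------------------------------------------------------------------------

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


def edf_quantization_step(phys_min: float, phys_max: float) -> float:
    """Amplitude resolution (μV per digital count) of a written EDF channel."""
    return (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)


def _edf_field(value: object, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        # numeric fields: shorten representation rather than corrupt the layout
        if isinstance(value, float):
            text = f"{value:.{max(width - 8, 1)}g}"
        text = text[:width]
    return text.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path: str | Path) -> Path:
    """Write *record* to an EDF file with 16-bit integer amplitude encoding.

    The physical range is chosen symmetric around zero and just wide enough
    for the data, so quantization error is at most half of
    :func:`edf_quantization_step` for that range.  One data record per second
    is used when ``fs`` is a whole number; otherwise a single data record
    holds the entire signal.
    """
    path = Path(path)
    samples = record.samples
    amp = float(np.max(np.abs(samples))) if samples.size else 0.0
    phys_max = max(amp, 1.0)
    phys_min = -phys_max

    fs = record.fs
    n = record.n_samples
    if float(fs).is_integer() and n % int(fs) == 0:
        spr = int(fs)  # samples per data record
        n_records = n // spr
        record_dur = "1"
    else:
        spr = n
        n_records = 1
        record_dur = f"{n / fs:.8g}"

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.round((samples - phys_min) * scale + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    header = b""
    header += _edf_field("0", 8)  # version
    header += _edf_field(record.subject_id, 80)  # patient id
    header += _edf_field(f"Startdate X {record.channel}", 80)  # recording id
    header += _edf_field("01.01.00", 8)  # start date
    header += _edf_field("00.00.00", 8)  # start time
    header += _edf_field(256 + 256, 8)  # header bytes (1 signal)
    header += _edf_field("", 44)  # reserved
    header += _edf_field(n_records, 8)
    header += _edf_field(record_dur, 8)
    header += _edf_field(1, 4)  # number of signals

    header += _edf_field(record.channel, 16)
    header += _edf_field("", 80)  # transducer
    header += _edf_field("uV", 8)  # physical dimension
    header += _edf_field(f"{phys_min:.6g}", 8)
    header += _edf_field(f"{phys_max:.6g}", 8)
    header += _edf_field(_EDF_DIG_MIN, 8)
    header += _edf_field(_EDF_DIG_MAX, 8)
    header += _edf_field("", 80)  # prefiltering
    header += _edf_field(spr, 8)
    header += _edf_field("", 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
    return path


def read_edf(
    path: str | Path,
    channel: str | None = None,
    subject_id: str | None = None,
) -> EEGRecord:
    """Read one channel of an EDF file as an :class:`EEGRecord` in μV.

    Parameters
    ----------
    path:
        EDF file location.
    channel:
        Channel label to select.  ``None`` takes the first channel.
    subject_id:
        Override the subject identity; defaults to the EDF patient-id field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    import mne  # deferred: mne import is heavyweight

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channel is None:
        channel = raw.ch_names[0]
    if channel not in raw.ch_names:
        raise KeyError(
            f"channel {channel!r} not in file (available: {raw.ch_names})"
        )
    data = raw.get_data(picks=[channel])[0]
    # mne returns SI units (volts) for EEG-like channels
    samples_uv = data * 1e6
    if subject_id is None:
        subject_info = raw.info.get("subject_info") or {}
        subject_id = str(
            subject_info.get("his_id") or subject_info.get("last_name") or "S0"
        )
    return EEGRecord(
        samples=samples_uv,
        fs=float(raw.info["sfreq"]),
        channel=channel,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

_CSV_HEADER = ("class", "onset", "duration", "scorer")


def read_annotations(
    path: str | Path,
    dialect: str = "csv",
    event_class: EventClass | str | None = None,
) -> list[EventAnnotation]:
    """Read an event annotation table, sorted by onset.

    ``dialect="csv"`` expects a header ``class,onset,duration[,scorer]``.
    ``dialect="dreams_txt"`` expects two whitespace-separated numeric columns
    (onset, duration); *event_class* must then be supplied by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    lines = path.read_text().splitlines()

    annotations: list[EventAnnotation] = []
    if dialect == "csv":
        if not lines:
            raise ValueError(f"{path}: empty file, expected a CSV header")
        header = tuple(h.strip().lower() for h in lines[0].split(","))
        if header[:3] != _CSV_HEADER[:3]:
            raise ValueError(
                f"{path}: bad CSV header {lines[0]!r}; expected "
                "'class,onset,duration[,scorer]'"
            )
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 fields, got {line!r}")
            try:
                onset, duration = float(parts[1]), float(parts[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric onset/duration in {line!r}"
                ) from None
            scorer = parts[3] if len(parts) > 3 and parts[3] else None
            try:
                annotations.append(
                    EventAnnotation(parts[0], onset, duration, scorer=scorer)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    elif dialect == "dreams_txt":
        if event_class is None:
            raise ValueError("dreams_txt dialect requires event_class")
        cls = _as_event_class(event_class)
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'onset duration', got {line!r}"
                )
            try:
                onset, duration = float(parts[0]), float(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value in {line!r}"
                ) from None
            try:
                annotations.append(EventAnnotation(cls, onset, duration))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'dreams_txt'")

    annotations.sort(key=lambda a: a.onset)
    return annotations


def write_annotations(
    annotations: Iterable[EventAnnotation], path: str | Path
) -> Path:
    """Write annotations as ``class,onset,duration,scorer`` CSV.

    Onset and duration are serialized with ``repr`` so that
    ``read_annotations(write_annotations(A)) == A`` exactly.
    """
    path = Path(path)
    rows = ["class,onset,duration,scorer"]
    for ann in annotations:
        rows.append(
            f"{ann.event_class.value},{ann.onset!r},{ann.duration!r},"
            f"{ann.scorer if ann.scorer is not None else ''}"
        )
    path.write_text("\n".join(rows) + "\n")
    return path


def merge_scorers(
    annotations: Sequence[EventAnnotation], policy: str = "union"
) -> list[EventAnnotation]:
    """Reconcile annotations from multiple scorers of the same record.

    ``policy="union"`` (default) merges overlapping same-class intervals into
    their union; ``policy="intersection"`` keeps, for each overlapping pair
    from two different scorers, the intersected interval.  With a single
    scorer the input is returned sorted and otherwise unchanged.
    """
    if policy not in ("union", "intersection"):
        raise ValueError(f"unknown merge policy {policy!r}")
    out: list[EventAnnotation] = []
    for cls in EventClass:
        cls_anns = sorted(
            (a for a in annotations if a.event_class is cls), key=lambda a: a.onset
        )
        if not cls_anns:
            continue
        if policy == "union":
            cur_on, cur_off = cls_anns[0].onset, cls_anns[0].offset
            for ann in cls_anns[1:]:
                if ann.onset <= cur_off:
                    cur_off = max(cur_off, ann.offset)
                else:
                    out.append(EventAnnotation(cls, cur_on, cur_off - cur_on))
                    cur_on, cur_off = ann.onset, ann.offset
            out.append(EventAnnotation(cls, cur_on, cur_off - cur_on))
        else:
            for i, a in enumerate(cls_anns):
                for b in cls_anns[i + 1 :]:
                    if b.onset >= a.offset:
                        break
                    if a.scorer == b.scorer:
                        continue
                    on, off = max(a.onset, b.onset), min(a.offset, b.offset)
                    if off > on:
                        out.append(EventAnnotation(cls, on, off - on))
    out.sort(key=lambda a: a.onset)
    return out
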