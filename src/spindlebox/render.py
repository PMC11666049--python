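"""Waveform-to-image rendering and bounding-box dataset construction.

An EEG record is cut into 5-second tumbling (non-overlapping) windows, each
window is rasterized as a polyline through its samples — one plotted point per
sample at the native sampling interval (5 ms at 200 Hz, 3.90625 ms at 256 Hz),
no resampling — and every annotated event interval becomes a pixel-space
bounding box: its x-extent is the affine image of the time interval, its
y-extent the pixel span of the event's own amplitude range plus a small pad.

Pixel conventions used throughout: origin at the top-left, 0-based
coordinates, boxes half-open ``[x_min, x_min + width) × [y_min, y_min +
height)``.  Export converts to each label format's own convention (COCO keeps
this one; Pascal VOC is 1-based inclusive).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

from .signal_io import EEGRecord, EventAnnotation, EventClass

__all__ = [
    "PlotGeometry",
    "BoundingBox",
    "Provenance",
    "LabeledImage",
    "segment_record",
    "time_to_px",
    "px_to_time",
    "amp_to_px",
    "px_to_amp",
    "render_window",
    "interval_to_bbox",
    "export_dataset",
    "import_labels",
    "balance_dataset",
]

#: category ids used in COCO exports
COCO_CATEGORY_IDS = {EventClass.SPINDLE: 1, EventClass.KCOMPLEX: 2}


class DegenerateBoxError(ValueError):
    """An event's bounding box collapsed to zero extent after clipping."""


@dataclass(frozen=True)
class PlotGeometry:
    """The affine time→x and amplitude→y maps of one rendered window.

    The drawable area is the canvas minus ``margin_px`` on each side; time
    ``t_start`` maps to its left edge and ``t_end`` to its right edge
    (exclusive).  Amplitude is mapped top-down: ``amp_max`` at the top of the
    drawable area, ``amp_min`` at the bottom.
    """

    width_px: int = 800
    height_px: int = 400
    t_start: float = 0.0
    t_end: float = 5.0
    amp_min: float = -120.0
    amp_max: float = 120.0
    margin_px: int = 0
    line_width_px: int = 2
    background: tuple[int, int, int] = (255, 255, 255)
    trace: tuple[int, int, int] = (20, 20, 120)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("canvas dimensions must be positive")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not self.amp_max > self.amp_min:
            raise ValueError("amp_max must exceed amp_min")
        if 2 * self.margin_px >= min(self.width_px, self.height_px):
            raise ValueError("margins must be below half the canvas dimensions")

    @property
    def window_s(self) -> float:
        return self.t_end - self.t_start

    @property
    def inner_width(self) -> float:
        return self.width_px - 2 * self.margin_px

    @property
    def inner_height(self) -> float:
        return self.height_px - 2 * self.margin_px


def time_to_px(geometry: PlotGeometry, t: float | np.ndarray) -> float | np.ndarray:
    """Map time (s, window-relative) to x pixel coordinate (float)."""
    frac = (np.asarray(t, dtype=float) - geometry.t_start) / geometry.window_s
    out = geometry.margin_px + frac * geometry.inner_width
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def px_to_time(geometry: PlotGeometry, x: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`time_to_px`."""
    frac = (np.asarray(x, dtype=float) - geometry.margin_px) / geometry.inner_width
    out = geometry.t_start + frac * geometry.window_s
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def amp_to_px(geometry: PlotGeometry, a: float | np.ndarray) -> float | np.ndarray:
    """Map amplitude (μV) to y pixel coordinate; larger amplitude is higher
    on the canvas, hence a smaller y (top-left origin)."""
    frac = (geometry.amp_max - np.asarray(a, dtype=float)) / (
        geometry.amp_max - geometry.amp_min
    )
    out = geometry.margin_px + frac * geometry.inner_height
    return float(out) if np.isscalar(a) or np.ndim(a) == 0 else out


def px_to_amp(geometry: PlotGeometry, y: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`amp_to_px`."""
    frac = (np.asarray(y, dtype=float) - geometry.margin_px) / geometry.inner_height
    out = geometry.amp_max - frac * (geometry.amp_max - geometry.amp_min)
    return float(out) if np.isscalar(y) or np.ndim(y) == 0 else out


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle, 0-based, half-open, top-left origin."""

    event_class: EventClass
    x_min: float
    y_min: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise DegenerateBoxError(
                f"box must have positive extent, got w={self.width}, h={self.height}"
            )

    @property
    def x_max(self) -> float:
        return self.x_min + self.width

    @property
    def y_max(self) -> float:
        return self.y_min + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    def is_inside(self, width_px: int, height_px: int, tol: float = 1e-9) -> bool:
        """Whether the box lies fully within a canvas of the given size."""
        return (
            self.x_min >= -tol
            and self.y_min >= -tol
            and self.x_max <= width_px + tol
            and self.y_max <= height_px + tol
        )


@dataclass(frozen=True)
class Provenance:
    subject_id: str
    window_index: int
    augmented: bool = False


@dataclass
class LabeledImage:
    """A rendered 5-s window, its ground-truth boxes, and how it was made."""

    pixels: np.ndarray  # (H, W, 3) uint8
    geometry: PlotGeometry
    boxes: list[BoundingBox]
    provenance: Provenance

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("pixels must be an (H, W, 3) uint8 array")
        h, w = px.shape[:2]
        for box in self.boxes:
            if not box.is_inside(w, h):
                raise ValueError(f"box {box} extends outside the {w}x{h} canvas")

    @property
    def name(self) -> str:
        suffix = "aug" if self.provenance.augmented else "raw"
        return (
            f"{self.provenance.subject_id}_w{self.provenance.window_index:05d}"
            f"_{suffix}"
        )

    def dominant_class(self) -> EventClass | None:
        """Majority event class of the boxes (first-seen wins ties)."""
        if not self.boxes:
            return None
        counts: dict[EventClass, int] = {}
        for b in self.boxes:
            counts[b.event_class] = counts.get(b.event_class, 0) + 1
        return max(counts, key=counts.get)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_record(
    record: EEGRecord,
    annotations: Sequence[EventAnnotation],
    window_s: float = 5.0,
    assign_policy: str = "majority",
) -> list[tuple[np.ndarray, list[EventAnnotation]]]:
    """Cut a record into tumbling windows with window-relative annotations.

    Windows are contiguous, non-overlapping, of exactly ``window_s`` seconds;
    a partial trailing window is dropped.  Each annotation is assigned to one
    window per *assign_policy*:

    ``"majority"``
        the window containing the largest share of the event's duration
        (ties go to the earlier window); the interval is then clipped to
        that window.
    ``"onset"``
        the window containing the event onset, clipped likewise.

    Returned onsets are re-expressed relative to the window start.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if record.duration_s < window_s:
        raise ValueError(
            f"record of {record.duration_s:.2f} s is shorter than one "
            f"{window_s} s window"
        )
    if assign_policy not in ("majority", "onset"):
        raise ValueError(f"unknown assign_policy {assign_policy!r}")

    samples_per_window = int(round(window_s * record.fs))
    n_windows = int(record.duration_s / window_s + 1e-9)
    per_window: list[list[EventAnnotation]] = [[] for _ in range(n_windows)]

    for ann in annotations:
        ann.validate_against(record)
        if assign_policy == "onset":
            w = int(ann.onset / window_s)
        else:
            first = int(ann.onset / window_s)
            last = int(np.nextafter(ann.offset, ann.onset) / window_s)
            overlaps = []
            for w_i in range(first, last + 1):
                lo = max(ann.onset, w_i * window_s)
                hi = min(ann.offset, (w_i + 1) * window_s)
                overlaps.append((hi - lo, -w_i))
            w = -max(overlaps)[1]
        if w >= n_windows:
            continue  # event lives in the dropped partial trailing window
        lo = max(ann.onset, w * window_s) - w * window_s
        hi = min(ann.offset, (w + 1) * window_s) - w * window_s
        if hi <= lo:
            continue
        per_window[w].append(
            EventAnnotation(ann.event_class, lo, hi - lo, scorer=ann.scorer)
        )

    out = []
    for w in range(n_windows):
        sl = record.samples[w * samples_per_window : (w + 1) * samples_per_window]
        out.append((sl, sorted(per_window[w], key=lambda a: a.onset)))
    return out


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def render_window(
    samples: np.ndarray, fs: float, geometry: PlotGeometry
) -> np.ndarray:
    """Rasterize one window as a polyline through its samples.

    One vertex per sample at ``t = t_start + i/fs`` — the native sampling
    interval of the recording; no resampling.  Deterministic: identical
    inputs give bit-identical rasters.
    """
    samples = np.asarray(samples, dtype=float)
    expected = int(round(geometry.window_s * fs))
    if samples.size != expected:
        raise ValueError(
            f"expected {expected} samples for a {geometry.window_s} s window "
            f"at {fs} Hz, got {samples.size}"
        )
    t = geometry.t_start + np.arange(samples.size) / fs
    xs = time_to_px(geometry, t)
    ys = amp_to_px(geometry, samples)
    img = Image.new("RGB", (geometry.width_px, geometry.height_px), geometry.background)
    draw = ImageDraw.Draw(img)
    pts = list(zip(xs.tolist(), ys.tolist()))
    draw.line(pts, fill=geometry.trace, width=geometry.line_width_px, joint="curve")
    return np.asarray(img, dtype=np.uint8)


def interval_to_bbox(
    annotation: EventAnnotation,
    samples: np.ndarray,
    fs: float,
    geometry: PlotGeometry,
    pad_frac: float = 0.05,
) -> BoundingBox:
    """Convert a window-relative event interval to a pixel bounding box.

    The x-extent is the affine image of ``[onset, onset + duration)``.  The
    y-extent spans the event's own amplitude range — the min and max sample
    value over the annotated interval — expanded by ``pad_frac`` of the
    canvas height on each side (which also absorbs the stroke width), then
    clipped to the canvas.
    """
    samples = np.asarray(samples, dtype=float)
    onset = annotation.onset
    offset = annotation.offset
    i0 = max(int(np.ceil((onset - geometry.t_start) * fs - 1e-9)), 0)
    i1 = min(int(np.floor((offset - geometry.t_start) * fs + 1e-9)), samples.size - 1)
    if i1 < i0:
        raise DegenerateBoxError(
            f"annotation [{onset}, {offset}) s covers no samples at fs={fs}"
        )
    seg = samples[i0 : i1 + 1]
    pad = pad_frac * geometry.height_px
    x0 = time_to_px(geometry, onset)
    x1 = time_to_px(geometry, offset)
    y0 = amp_to_px(geometry, float(seg.max())) - pad
    y1 = amp_to_px(geometry, float(seg.min())) + pad
    x0 = max(x0, 0.0)
    y0 = max(y0, 0.0)
    x1 = min(x1, float(geometry.width_px))
    y1 = min(y1, float(geometry.height_px))
    if x1 <= x0 or y1 <= y0:
        raise DegenerateBoxError(
            f"annotation [{onset}, {offset}) s maps outside the canvas"
        )
    return BoundingBox(annotation.event_class, x0, y0, x1 - x0, y1 - y0)


def render_dataset(
    record: EEGRecord,
    annotations: Sequence[EventAnnotation],
    geometry: PlotGeometry | None = None,
    window_s: float = 5.0,
    pad_frac: float = 0.05,
    assign_policy: str = "majority",
    keep_empty: bool = False,
) -> list[LabeledImage]:
    """Segment, rasterize and box a whole record in one pass.

    By default only windows containing at least one event are kept, matching
    how event-centred detection datasets are built; ``keep_empty=True``
    retains event-free windows as negative examples.
    """
    if geometry is None:
        geometry = PlotGeometry(t_end=window_s)
    if abs(geometry.window_s - window_s) > 1e-9:
        geometry = replace(geometry, t_start=0.0, t_end=window_s)
    images: list[LabeledImage] = []
    for w, (samples, anns) in enumerate(
        segment_record(record, annotations, window_s, assign_policy)
    ):
        if not anns and not keep_empty:
            continue
        pixels = render_window(samples, record.fs, geometry)
        boxes = []
        for ann in anns:
            try:
                boxes.append(interval_to_bbox(ann, samples, record.fs, geometry, pad_frac))
            except DegenerateBoxError:
                continue
        images.append(
            LabeledImage(pixels, geometry, boxes, Provenance(record.subject_id, w))
        )
    return images


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def export_dataset(
    images: Sequence[LabeledImage], fmt: str, out_dir: str | Path
) -> Path:
    """Write images as PNG plus labels in ``coco_json``, ``voc_xml`` or
    ``csv`` form.  Returns the label file path (for VOC, the directory of
    per-image XML files)."""
    if not images:
        raise ValueError("cannot export an empty dataset")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    names: list[str] = []
    seen: dict[str, int] = {}
    for im in images:
        stem = im.name
        k = seen.get(stem, 0)
        seen[stem] = k + 1
        name = f"{stem}.png" if k == 0 else f"{stem}_{k}.png"
        names.append(name)
        Image.fromarray(im.pixels).save(img_dir / name)

    if fmt == "csv":
        label_path = out_dir / "labels.csv"
        rows = ["image,class,x_min,y_min,width,height"]
        for im, name in zip(images, names):
            for b in im.boxes:
                rows.append(
                    f"{name},{b.event_class.value},{b.x_min!r},{b.y_min!r},"
                    f"{b.width!r},{b.height!r}"
                )
        label_path.write_text("\n".join(rows) + "\n")
        return label_path

    if fmt == "coco_json":
        label_path = out_dir / "labels.json"
        coco_images, coco_anns = [], []
        ann_id = 1
        for img_id, (im, name) in enumerate(zip(images, names), start=1):
            h, w = im.pixels.shape[:2]
            coco_images.append(
                {"id": img_id, "file_name": name, "width": w, "height": h}
            )
            for b in im.boxes:
                coco_anns.append(
                    {
                        "id": ann_id,
                        "image_id": img_id,
                        "category_id": COCO_CATEGORY_IDS[b.event_class],
                        "bbox": [b.x_min, b.y_min, b.width, b.height],
                        "area": b.area,
                        "iscrowd": 0,
                    }
                )
                ann_id += 1
        doc = {
            "images": coco_images,
            "annotations": coco_anns,
            "categories": [
                {"id": cid, "name": cls.value}
                for cls, cid in COCO_CATEGORY_IDS.items()
            ],
        }
        label_path.write_text(json.dumps(doc, indent=1))
        return label_path

    if fmt == "voc_xml":
        label_dir = out_dir / "annotations"
        label_dir.mkdir(exist_ok=True)
        for im, name in zip(images, names):
            h, w = im.pixels.shape[:2]
            root = ET.Element("annotation")
            ET.SubElement(root, "filename").text = name
            size = ET.SubElement(root, "size")
            ET.SubElement(size, "width").text = str(w)
            ET.SubElement(size, "height").text = str(h)
            ET.SubElement(size, "depth").text = "3"
            for b in im.boxes:
                obj = ET.SubElement(root, "object")
                ET.SubElement(obj, "name").text = b.event_class.value
                bb = ET.SubElement(obj, "bndbox")
                # VOC is 1-based with inclusive max pixel
                ET.SubElement(bb, "xmin").text = repr(b.x_min + 1)
                ET.SubElement(bb, "ymin").text = repr(b.y_min + 1)
                ET.SubElement(bb, "xmax").text = repr(b.x_max)
                ET.SubElement(bb, "ymax").text = repr(b.y_max)
            ET.ElementTree(root).write(
                label_dir / f"{Path(name).stem}.xml", encoding="unicode"
            )
        return label_dir

    raise ValueError(f"unknown export format {fmt!r}")


def import_labels(path: str | Path, fmt: str) -> dict[str, list[BoundingBox]]:
    """Read boxes back from an exported label file/directory.

    Returns a mapping from image file name to its boxes, in the package's
    own 0-based half-open convention (inverse of :func:`export_dataset`).
    """
    path = Path(path)
    out: dict[str, list[BoundingBox]] = {}
    if fmt == "csv":
        lines = path.read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            name, cls, x0, y0, w, h = line.split(",")
            out.setdefault(name, []).append(
                BoundingBox(EventClass(cls), float(x0), float(y0), float(w), float(h))
            )
        return out
    if fmt == "coco_json":
        doc = json.loads(path.read_text())
        id_to_name = {im["id"]: im["file_name"] for im in doc["images"]}
        cat_to_cls = {c["id"]: EventClass(c["name"]) for c in doc["categories"]}
        for im in doc["images"]:
            out.setdefault(im["file_name"], [])
        for ann in doc["annotations"]:
            x0, y0, w, h = ann["bbox"]
            out[id_to_name[ann["image_id"]]].append(
                BoundingBox(cat_to_cls[ann["category_id"]], x0, y0, w, h)
            )
        return out
    if fmt == "voc_xml":
        for xml_file in sorted(path.glob("*.xml")):
            root = ET.parse(xml_file).getroot()
            name = root.findtext("filename")
            boxes = []
            for obj in root.iter("object"):
                cls = EventClass(obj.findtext("name"))
                bb = obj.find("bndbox")
                xmin = float(bb.findtext("xmin")) - 1
                ymin = float(bb.findtext("ymin")) - 1
                xmax = float(bb.findtext("xmax"))
                ymax = float(bb.findtext("ymax"))
                boxes.append(BoundingBox(cls, xmin, ymin, xmax - xmin, ymax - ymin))
            out[name] = boxes
        return out
    raise ValueError(f"unknown import format {fmt!r}")


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------


def balance_dataset(
    images: Sequence[LabeledImage],
    strategy: str,
    rng: np.random.Generator,
    augment_params=None,
) -> list[LabeledImage]:
    """Balance per-class image counts the way detection datasets are.

    ``"undersample_majority"`` randomly drops majority-class images down to
    the minority count (e.g. 1044 spindle + 271 K-complex → 271 + 271);
    ``"augment_minority"`` adds augmented copies of minority images until the
    counts match (271 → 1044), marking copies ``provenance.augmented``.
    Images are grouped by their dominant box class; box-free images pass
    through untouched.
    """
    if strategy not in ("undersample_majority", "augment_minority"):
        raise ValueError(f"unknown balancing strategy {strategy!r}")
    groups: dict[EventClass, list[LabeledImage]] = {c: [] for c in EventClass}
    passthrough: list[LabeledImage] = []
    for im in images:
        cls = im.dominant_class()
        (groups[cls] if cls is not None else passthrough).append(im)
    nonempty = {c: g for c, g in groups.items() if g}
    if len(nonempty) < 2:
        return list(images)
    counts = {c: len(g) for c, g in nonempty.items()}
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    if counts[minority] == counts[majority]:
        return list(images)

    out = list(passthrough)
    if strategy == "undersample_majority":
        for cls, group in nonempty.items():
            if cls is majority:
                idx = rng.choice(len(group), size=counts[minority], replace=False)
                out.extend(group[i] for i in sorted(idx))
            else:
                out.extend(group)
        return out

    from .augment import AugmentParams, augment  # deferred: avoids cycle

    params = augment_params or AugmentParams()
    out.extend(im for g in nonempty.values() for im in g)
    group = nonempty[minority]
    if not group:
        raise ValueError("cannot augment a class with zero source images")
    deficit = counts[majority] - counts[minority]
    for k in range(deficit):
        src = group[int(rng.integers(len(group)))]
        out.append(augment(src, params, rng))
    return out
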