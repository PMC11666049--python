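"""Optional adapter between exported datasets and external object detectors.

Training deep detectors (Faster R-CNN / YOLO families) is delegated to an
external backend — those networks are consumed, not re-implemented.  The
harness's own responsibilities are small and fully testable without any
backend installed:

* hold the training hyperparameters (SGD with momentum 0.9, initial learning
  rate 0.001, batch size 2, L2 regularization 0.0001, at most 30 epochs) and
  round-trip them losslessly through JSON for provenance;
* hand a COCO-format dataset directory to the chosen backend and collect its
  test-split detections in the evaluation module's input format;
* fail with a distinct capability error (not a crash) when the requested
  backend is unavailable, so the rest of the package never depends on it.

A built-in ``"oracle"`` backend — explicitly non-learned, it simply echoes
the ground-truth boxes of the test split at full confidence — exists so the
dataset → detections → evaluation plumbing can be smoke-tested end to end.
"""

from __future__ import annotations

import importlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .evaluate import Detection
from .render import import_labels

__all__ = ["TrainConfig", "BackendUnavailableError", "run_training"]


class BackendUnavailableError(RuntimeError):
    """The requested detector backend is not installed or not importable."""


@dataclass(frozen=True)
class TrainConfig:
    """Detector-training hyperparameters (SGDM defaults)."""

    detector: str = "oracle"
    backbone: str = "none"
    max_epochs: int = 30
    learning_rate: float = 0.001
    batch_size: int = 2
    l2_regularization: float = 0.0001
    momentum: float = 0.9
    split: tuple[float, float, float] = (0.6, 0.1, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainConfig":
        doc = json.loads(Path(path).read_text())
        doc["split"] = tuple(doc["split"])
        return cls(**doc)


def _oracle_backend(dataset_dir: Path, config: TrainConfig) -> list[Detection]:
    """Echo the dataset's own ground truth as detections (confidence 1).

    Not a learned model and not a performance claim — a plumbing check that
    exercises the dataset → detections → evaluation path.
    """
    labels = import_labels(dataset_dir / "labels.json", "coco_json")
    detections = []
    for image_name, boxes in labels.items():
        for box in boxes:
            detections.append(Detection(box, box.event_class, 1.0, image_name))
    return detections


def _torchvision_backend(dataset_dir: Path, config: TrainConfig) -> list[Detection]:
    try:
        importlib.import_module("torchvision")
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise BackendUnavailableError(
            "the 'torchvision' backend needs the optional training extras; "
            "install torch and torchvision to enable it"
        ) from exc
    raise BackendUnavailableError(  # pragma: no cover
        "torchvision training loop not bundled; supply a custom backend "
        "callable to run_training(..., backend=...)"
    )


_BACKENDS = {
    "oracle": _oracle_backend,
    "torchvision": _torchvision_backend,
}


def run_training(
    dataset_dir: str | Path,
    config: TrainConfig,
    backend=None,
    out_dir: str | Path | None = None,
) -> list[Detection]:
    """Run a detector backend over an exported COCO dataset directory.

    Parameters
    ----------
    dataset_dir:
        Directory produced by :func:`spindlebox.render.export_dataset` with
        ``coco_json`` labels.
    config:
        Hyperparameters; logged verbatim next to the detections.
    backend:
        A callable ``(dataset_dir, config) -> list[Detection]``; if ``None``
        the named backend from ``config.detector`` is used.
    out_dir:
        If given, the resolved config (``train_config.json``) and detections
        (``detections.json``, COCO-results style) are written there.

    Raises
    ------
    BackendUnavailableError
        If the named backend cannot run in this installation.
    """
    dataset_dir = Path(dataset_dir)
    if not (dataset_dir / "labels.json").exists():
        raise FileNotFoundError(f"no COCO labels.json under {dataset_dir}")
    if backend is None:
        try:
            backend = _BACKENDS[config.detector]
        except KeyError:
            raise BackendUnavailableError(
                f"unknown detector backend {config.detector!r}; "
                f"available: {sorted(_BACKENDS)}"
            ) from None
    detections = backend(dataset_dir, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_json(out_dir / "train_config.json")
        results = [
            {
                "image_id": d.image_id,
                "category": d.event_class.value,
                "bbox": [d.box.x_min, d.box.y_min, d.box.width, d.box.height],
                "score": d.confidence,
            }
            for d in detections
        ]
        (out_dir / "detections.json").write_text(json.dumps(results, indent=1))
    return detections
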