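"""Independent reference implementations used to cross-check the metrics."""

import numpy as np

from spindlebox.evaluate import iou
from spindlebox.render import BoundingBox
from spindlebox.signal_io import EventClass


def box(x, y, w, h, cls=EventClass.SPINDLE):
    return BoundingBox(cls, float(x), float(y), float(w), float(h))


def random_box(rng, span=100.0):
    x, y = rng.uniform(0, span, size=2)
    w, h = rng.uniform(5, span / 2, size=2)
    return box(x, y, w, h)


def greedy_match_oracle(detections, truths, threshold):
    """Set-based re-implementation of confidence-ordered greedy matching."""
    remaining = {img: set(range(len(b))) for img, b in truths.items()}
    flags = []
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    for i in order:
        d = detections[i]
        candidates = [
            (iou(d.box, truths[d.image_id][j]), -j)
            for j in remaining.get(d.image_id, ())
        ]
        best = max(candidates) if candidates else (0.0, 0)
        if candidates and best[0] >= threshold:
            remaining[d.image_id].discard(-best[1])
            flags.append(True)
        else:
            flags.append(False)
    fn = sum(len(s) for s in remaining.values())
    return flags, fn


def ap_fine_grid_oracle(curve, resolution=1_000_000):
    """Right-endpoint Riemann sum of the precision envelope, fraction scale.

    The envelope is monotone non-increasing, so the sum's error is bounded
    by its total variation over the grid spacing: at most 1/resolution.
    """
    r = np.asarray(curve.recall)
    p = np.asarray(curve.precision)
    env = np.maximum.accumulate(p[::-1])[::-1]
    grid = np.arange(1, resolution + 1) / resolution
    idx = np.searchsorted(r, grid, side="left")
    vals = np.where(idx < env.size, env[np.minimum(idx, env.size - 1)], 0.0)
    return vals.sum() / resolution
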