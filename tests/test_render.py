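import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spindlebox.render import (
    BoundingBox,
    DegenerateBoxError,
    LabeledImage,
    PlotGeometry,
    Provenance,
    amp_to_px,
    balance_dataset,
    export_dataset,
    import_labels,
    interval_to_bbox,
    px_to_amp,
    px_to_time,
    render_window,
    segment_record,
    time_to_px,
)
from spindlebox.signal_io import EEGRecord, EventAnnotation, EventClass


@pytest.fixture
def unit_geometry():
    """1000x400 canvas with no margins over a [0, 5) s window."""
    return PlotGeometry(width_px=1000, height_px=400, t_start=0.0, t_end=5.0,
                        margin_px=0)


class TestSegmentation:
    def test_window_count_floor(self):
        rec = EEGRecord(np.zeros(360000), fs=200.0)  # 1800 s
        assert len(segment_record(rec, [], window_s=5.0)) == 360

    def test_partial_trailing_window_dropped(self):
        rec = EEGRecord(np.zeros(2300), fs=200.0)  # 11.5 s
        windows = segment_record(rec, [], window_s=5.0)
        assert len(windows) == 2
        assert all(w[0].size == 1000 for w in windows)

    def test_majority_assignment_crosses_boundary(self):
        rec = EEGRecord(np.zeros(4000), fs=200.0)  # 20 s
        ann = EventAnnotation("spindle", 4.8, 1.0)  # 0.2 s in w0, 0.8 s in w1
        windows = segment_record(rec, [ann], window_s=5.0)
        assert windows[0][1] == []
        (rel,) = windows[1][1]
        assert rel.onset == pytest.approx(0.0)
        assert rel.duration == pytest.approx(0.8)  # clipped to its window

    def test_fully_contained_annotation_unchanged(self):
        rec = EEGRecord(np.zeros(4000), fs=200.0)
        ann = EventAnnotation("kcomplex", 1.0, 1.65)
        (w0, anns0), *rest = segment_record(rec, [ann], window_s=5.0)
        assert anns0 == [ann]

    def test_onset_policy(self):
        rec = EEGRecord(np.zeros(4000), fs=200.0)
        ann = EventAnnotation("spindle", 4.8, 1.0)
        windows = segment_record(rec, [ann], window_s=5.0, assign_policy="onset")
        (rel,) = windows[0][1]
        assert rel.onset == pytest.approx(4.8)
        assert rel.duration == pytest.approx(0.2)

    def test_too_short_record_rejected(self):
        rec = EEGRecord(np.zeros(400), fs=200.0)  # 2 s
        with pytest.raises(ValueError, match="shorter"):
            segment_record(rec, [], window_s=5.0)


class TestAffineMaps:
    def test_time_endpoints_and_midpoint(self, unit_geometry):
        assert time_to_px(unit_geometry, 0.0) == 0.0
        assert time_to_px(unit_geometry, 2.5) == 500.0
        assert time_to_px(unit_geometry, 5.0) == 1000.0  # exclusive edge

    def test_amplitude_is_monotone_decreasing(self, unit_geometry):
        top = amp_to_px(unit_geometry, unit_geometry.amp_max)
        bottom = amp_to_px(unit_geometry, unit_geometry.amp_min)
        assert top == 0.0 and bottom == 400.0
        a = np.linspace(unit_geometry.amp_min, unit_geometry.amp_max, 50)
        assert np.all(np.diff(amp_to_px(unit_geometry, a)) < 0)

    def test_round_trip_within_half_pixel_time(self, unit_geometry, rng):
        t = rng.uniform(0.0, 5.0, size=1000)
        back = px_to_time(unit_geometry, time_to_px(unit_geometry, t))
        half_pixel_s = (5.0 / unit_geometry.width_px) / 2
        assert np.max(np.abs(back - t)) <= half_pixel_s

    def test_amp_round_trip(self, unit_geometry, rng):
        a = rng.uniform(-120, 120, size=200)
        back = px_to_amp(unit_geometry, amp_to_px(unit_geometry, a))
        assert np.allclose(back, a, atol=1e-9)

    def test_margins_shift_the_map(self):
        g = PlotGeometry(width_px=1000, height_px=400, margin_px=50)
        assert time_to_px(g, 0.0) == 50.0
        assert time_to_px(g, 5.0) == 950.0

    @settings(derandomize=True, deadline=None)
    @given(
        t=st.floats(0.0, 5.0),
        width=st.integers(10, 4000),
        margin=st.integers(0, 4),
    )
    def test_round_trip_property(self, t, width, margin):
        g = PlotGeometry(width_px=width, height_px=400, margin_px=margin)
        half_pixel_s = (g.window_s / g.inner_width) / 2
        assert abs(px_to_time(g, time_to_px(g, t)) - t) <= half_pixel_s


class TestRenderWindow:
    def test_flat_zero_trace_is_horizontal_line(self, unit_geometry):
        px = render_window(np.zeros(1000), 200.0, unit_geometry)
        trace_rows = np.flatnonzero(
            np.any(np.any(px != 255, axis=2), axis=1)
        )
        y_center = amp_to_px(unit_geometry, 0.0)
        assert trace_rows.size > 0
        assert np.all(np.abs(trace_rows - y_center) <= unit_geometry.line_width_px)

    def test_256hz_window_has_1280_points(self, unit_geometry):
        # 5 s at 256 Hz: 1280 samples plotted 3.90625 ms apart
        samples = np.sin(np.arange(1280) / 20.0) * 30
        px = render_window(samples, 256.0, unit_geometry)
        assert px.shape == (400, 1000, 3)
        with pytest.raises(ValueError, match="expected 1280"):
            render_window(samples[:-1], 256.0, unit_geometry)

    def test_deterministic(self, unit_geometry, rng):
        samples = rng.normal(0, 20, size=1000)
        a = render_window(samples, 200.0, unit_geometry)
        b = render_window(samples, 200.0, unit_geometry)
        assert np.array_equal(a, b)


class TestIntervalToBBox:
    def test_x_extent_is_affine_image_of_interval(self, unit_geometry):
        samples = np.zeros(1000)
        samples[200:400] = 40.0
        ann = EventAnnotation("spindle", 1.0, 1.0)
        box = interval_to_bbox(ann, samples, 200.0, unit_geometry, pad_frac=0.0)
        assert box.x_min == 200.0
        assert box.width == 200.0

    def test_box_covers_rendered_event_pixels(self, unit_geometry):
        # flat background + one K-complex: every trace pixel within the
        # event's x-span must fall inside the (padded) box
        from spindlebox.simulate import kcomplex_waveform

        samples = np.zeros(1000)
        wave = kcomplex_waveform(200.0)
        samples[300 : 300 + wave.size] = wave
        ann = EventAnnotation("kcomplex", 1.5, 1.65)
        box = interval_to_bbox(ann, samples, 200.0, unit_geometry, pad_frac=0.05)
        px = render_window(samples, 200.0, unit_geometry)
        nonbg = np.any(px != 255, axis=2)
        x0, x1 = int(np.ceil(box.x_min)), int(np.floor(box.x_max))
        for x in range(x0, x1):
            rows = np.flatnonzero(nonbg[:, x])
            assert rows.size > 0
            assert rows.min() >= np.floor(box.y_min)
            assert rows.max() <= np.ceil(box.y_max)

    def test_event_clipped_at_window_edge_is_flush(self, unit_geometry):
        samples = np.full(1000, 10.0)
        ann = EventAnnotation("spindle", 0.0, 0.5)
        box = interval_to_bbox(ann, samples, 200.0, unit_geometry)
        assert box.x_min == 0.0
        assert box.is_inside(1000, 400)

    def test_degenerate_interval_raises(self, unit_geometry):
        samples = np.zeros(1000)
        ann = EventAnnotation("spindle", 4.999, 0.0001)
        with pytest.raises(DegenerateBoxError):
            interval_to_bbox(ann, samples, 200.0, unit_geometry)


def _tiny_image(cls, idx, w=64, h=32, augmented=False):
    geometry = PlotGeometry(width_px=w, height_px=h)
    pixels = np.full((h, w, 3), 255, dtype=np.uint8)
    box = BoundingBox(cls, 10.0, 5.0, 20.0, 10.0)
    return LabeledImage(pixels, geometry, [box], Provenance("s", idx, augmented))


class TestExportImport:
    @pytest.fixture
    def images(self, rendered):
        _, _, _, images = rendered
        return images

    @pytest.mark.parametrize("fmt", ["csv", "coco_json", "voc_xml"])
    def test_round_trip_preserves_boxes(self, images, fmt, tmp_path):
        label_path = export_dataset(images, fmt, tmp_path / fmt)
        back = import_labels(label_path, fmt)
        assert len(back) == len(images)
        for im in images:
            got = back[f"{im.name}.png"]
            assert len(got) == len(im.boxes)
            for b_in, b_out in zip(im.boxes, got):
                assert b_out.event_class is b_in.event_class
                # csv/coco serialize coordinates verbatim; voc goes through
                # the 1-based inclusive convention (one ulp of arithmetic)
                tol = 0.0 if fmt != "voc_xml" else 1e-9
                assert abs(b_out.x_min - b_in.x_min) <= tol
                assert abs(b_out.y_min - b_in.y_min) <= tol
                assert abs(b_out.width - b_in.width) <= tol
                assert abs(b_out.height - b_in.height) <= tol

    def test_coco_area_and_counts(self, tmp_path):
        im = _tiny_image(EventClass.SPINDLE, 0)
        path = export_dataset([im], "coco_json", tmp_path)
        import json

        doc = json.loads(path.read_text())
        assert len(doc["images"]) == 1
        (ann,) = doc["annotations"]
        assert ann["area"] == 20.0 * 10.0

    def test_negative_example_image_retained(self, tmp_path):
        geometry = PlotGeometry(width_px=64, height_px=32)
        empty = LabeledImage(
            np.full((32, 64, 3), 255, dtype=np.uint8), geometry, [],
            Provenance("s", 9),
        )
        path = export_dataset([empty], "coco_json", tmp_path)
        back = import_labels(path, "coco_json")
        assert back == {f"{empty.name}.png": []}

    def test_empty_dataset_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_dataset([], "csv", tmp_path)


class TestBalanceDataset:
    def test_undersample_majority(self, rng):
        images = [_tiny_image(EventClass.SPINDLE, i) for i in range(20)]
        images += [_tiny_image(EventClass.KCOMPLEX, 100 + i) for i in range(5)]
        out = balance_dataset(images, "undersample_majority", rng)
        by_class = {c: 0 for c in EventClass}
        for im in out:
            by_class[im.dominant_class()] += 1
        assert by_class == {EventClass.SPINDLE: 5, EventClass.KCOMPLEX: 5}

    def test_augment_minority(self, rng):
        images = [_tiny_image(EventClass.SPINDLE, i) for i in range(12)]
        images += [_tiny_image(EventClass.KCOMPLEX, 100 + i) for i in range(3)]
        out = balance_dataset(images, "augment_minority", rng)
        kc = [im for im in out if im.dominant_class() is EventClass.KCOMPLEX]
        assert len(kc) == 12
        assert sum(im.provenance.augmented for im in kc) == 9
        assert len([im for im in out if im.dominant_class() is EventClass.SPINDLE]) == 12

    def test_already_balanced_unchanged(self, rng):
        images = [_tiny_image(EventClass.SPINDLE, 0), _tiny_image(EventClass.KCOMPLEX, 1)]
        for strategy in ("undersample_majority", "augment_minority"):
            assert balance_dataset(images, strategy, rng) == images

    def test_unknown_strategy(self, rng):
        with pytest.raises(ValueError):
            balance_dataset([_tiny_image(EventClass.SPINDLE, 0)], "oversample", rng)
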