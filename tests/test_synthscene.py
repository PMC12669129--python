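"""Scene generator: effective-pair arithmetic, rendering, truth integrity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenostage.detect import iou
from phenostage.synthscene import (
    ANOMALIES,
    DARK_LUMINANCE_CAP,
    InvalidSpecError,
    PlantSpec,
    effective_pairs,
    make_corpus,
    random_scene,
    read_truth_csv,
    render_plant,
    render_scene,
)


class TestEffectivePairs:
    @pytest.mark.parametrize(
        "n,missing,expected",
        [
            (4, set(), 4),
            (4, {(1, "left")}, 4),  # single missing leaf: pair still intact
            (4, {(1, "left"), (1, "right"), (2, "right")}, 3),  # both gone: -1
            (0, set(), 0),
            (3, {(0, "left"), (0, "right"), (1, "left"), (1, "right")}, 1),
        ],
    )
    def test_counting_rule(self, n, missing, expected):
        assert effective_pairs(n, missing) == expected

    def test_out_of_range_pair_index_rejected(self):
        with pytest.raises(InvalidSpecError):
            effective_pairs(2, {(5, "left")})

    @given(
        n=st.integers(0, 8),
        marks=st.sets(st.tuples(st.integers(0, 7), st.sampled_from(["left", "right"]))),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, n, marks):
        """More missing leaves never increases the count; result in [0, n]."""
        marks = {(k, s) for k, s in marks if k < n}
        full = effective_pairs(n, marks)
        for sub in (set(), set(list(marks)[: len(marks) // 2])):
            assert effective_pairs(n, sub) >= full
        assert 0 <= full <= n


class TestRenderPlant:
    def _blank(self):
        return np.zeros((200, 200, 3), dtype=np.float64)

    def test_stub_plant_draws_only_apex(self):
        spec = PlantSpec(center_xy=(100, 100), n_pairs=0, leaf_length_px=30)
        _, box = render_plant(spec, self._blank())
        w, h = box[2] - box[0], box[3] - box[1]
        assert w <= 12 and h <= 12  # apex disk extent only

    def test_full_rosette_box_contains_leaves(self):
        spec = PlantSpec(center_xy=(100, 100), n_pairs=3, leaf_length_px=30)
        canvas = self._blank()
        canvas, box = render_plant(spec, canvas)
        drawn = np.argwhere(canvas.sum(axis=2) > 0)
        assert box[0] <= drawn[:, 1].min() and drawn[:, 1].max() < box[2]
        assert box[1] <= drawn[:, 0].min() and drawn[:, 0].max() < box[3]
        # rosette spans roughly twice the leaf length
        assert box[2] - box[0] > 1.5 * spec.leaf_length_px

    def test_missing_pair_shrinks_painted_area(self):
        full = PlantSpec(center_xy=(100, 100), n_pairs=3, leaf_length_px=30)
        holey = PlantSpec(
            center_xy=(100, 100), n_pairs=3, leaf_length_px=30,
            missing_leaves=frozenset({(0, "left"), (0, "right")}),
        )
        area_full = (render_plant(full, self._blank())[0].sum(axis=2) > 0).sum()
        area_holey = (render_plant(holey, self._blank())[0].sum(axis=2) > 0).sum()
        assert area_holey < area_full
        assert effective_pairs(holey.n_pairs, holey.missing_leaves) == 2

    def test_invalid_leaf_length_rejected(self):
        with pytest.raises(InvalidSpecError):
            PlantSpec(center_xy=(0, 0), n_pairs=1, leaf_length_px=0.0)


class TestRenderScene:
    def test_deterministic_for_fixed_seed(self):
        spec = random_scene(7)
        img1, t1 = render_scene(spec)
        img2, t2 = render_scene(spec)
        assert np.array_equal(img1, img2)
        assert t1.boxes == t2.boxes and t1.pairs == t2.pairs

    def test_clean_scene_truth_boxes_disjoint(self):
        _, truth = render_scene(random_scene(3))
        assert len(truth.boxes) == 8
        for i in range(8):
            for j in range(i + 1, 8):
                assert iou(truth.boxes[i], truth.boxes[j]) == 0.0

    def test_foliage_pixels_inside_truth_boxes(self):
        """Every painted pixel of plant i lies inside boxes[i] (clean scene)."""
        img, truth, owner = render_scene(random_scene(9), return_owner=True)
        for i, (x1, y1, x2, y2) in enumerate(truth.boxes):
            rows, cols = np.nonzero(owner == i)
            assert rows.size > 0
            assert x1 <= cols.min() and cols.max() < x2
            assert y1 <= rows.min() and rows.max() < y2

    def test_apex_remains_visible(self):
        """The apex disk of each plant is owned by that plant in the final
        per-pixel z-order (no leaf of any plant overdraws it)."""
        spec = random_scene(4)
        _, truth, owner = render_scene(spec, return_owner=True)
        for i, plant in enumerate(spec.plants):
            cx, cy = plant.center_xy
            assert owner[int(round(cy)), int(round(cx))] == i

    def test_reading_order_is_row_major(self):
        spec = random_scene(2)
        _, truth = render_scene(spec)
        ranked = sorted(range(8), key=lambda i: truth.order[i])
        rows = [truth.row_of[i] for i in ranked]
        assert rows == sorted(rows)  # top row first, bottom last
        for r in range(3):
            cxs = [
                (truth.boxes[i][0] + truth.boxes[i][2]) / 2
                for i in ranked
                if truth.row_of[i] == r
            ]
            assert cxs == sorted(cxs)  # left to right within each row

    def test_empty_pot_scene_has_seven_plants(self):
        _, truth = render_scene(random_scene(5, anomaly="empty_pot"))
        assert len(truth.boxes) == 7

    def test_multi_seedling_scene_has_extra_overlapping_plant(self):
        _, truth = render_scene(random_scene(5, anomaly="multi_seedling"))
        assert len(truth.boxes) == 9
        assert max(
            iou(a, b) for i, a in enumerate(truth.boxes) for b in truth.boxes[i + 1 :]
        ) > 0.0

    def test_dark_frame_is_near_black_with_empty_truth(self):
        img, truth = render_scene(random_scene(5, anomaly="dark_frame"))
        assert img.mean() <= DARK_LUMINANCE_CAP
        assert truth.boxes == [] and truth.pairs == []

    def test_out_of_frame_box_extends_beyond_canvas(self):
        spec = random_scene(5, anomaly="out_of_frame")
        _, truth = render_scene(spec)
        assert any(b[0] < 0 for b in truth.boxes)


class TestMakeCorpus:
    def test_clean_corpus_box_count(self, tmp_path):
        scenes = make_corpus(10, tmp_path, anomaly_rates={}, seed=0)
        assert len(scenes) == 10
        assert sum(len(t.boxes) for _, t in scenes) == 80

    def test_anomaly_rates_are_exact_counts(self, tmp_path):
        scenes = make_corpus(30, tmp_path, anomaly_rates={"dark_frame": 0.1}, seed=1)
        assert sum(t.anomaly == "dark_frame" for _, t in scenes) == 3

    def test_truth_csv_roundtrip_and_determinism(self, tmp_path):
        a = make_corpus(6, tmp_path / "a", anomaly_rates={"empty_pot": 0.34}, seed=4)
        b = make_corpus(6, tmp_path / "b", anomaly_rates={"empty_pot": 0.34}, seed=4)
        csv_a = (tmp_path / "a" / "truth.csv").read_text()
        csv_b = (tmp_path / "b" / "truth.csv").read_text()
        assert csv_a == csv_b
        loaded = read_truth_csv(tmp_path / "a" / "truth.csv")
        for i, (_, truth) in enumerate(a):
            assert loaded[i].pairs == truth.pairs
            assert loaded[i].anomaly == truth.anomaly
            assert np.allclose(loaded[i].boxes, truth.boxes)

    def test_bad_rates_rejected(self, tmp_path):
        with pytest.raises(InvalidSpecError):
            make_corpus(5, tmp_path, anomaly_rates={"dark_frame": 0.9, "empty_pot": 0.9})
        with pytest.raises(InvalidSpecError):
            make_corpus(5, tmp_path, anomaly_rates={"bogus": 0.1})
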