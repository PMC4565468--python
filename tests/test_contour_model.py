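import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eptplan.contour_model import (ContourEdit, SliceContour, apply_edits,
                                   extract_slice_contours,
                                   manual_contour_ingest, point_influence,
                                   rasterize_contours, refine_contour,
                                   simplify_contour)
from eptplan.core import LabelMask, dice


def slice_mask(binary2d, nz=3, k=1, label=1, name="tumor"):
    labels = np.zeros(binary2d.shape + (nz,), dtype=np.int16)
    labels[:, :, k] = label * binary2d
    return LabelMask(labels, {label: name})


def circle_contour(n=100, r=20.0, center=(32.0, 32.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
    return SliceContour(0, pts)


class TestExtract:
    def test_square_area_matches_pixels(self):
        sq = np.zeros((20, 20), dtype=bool)
        sq[5:15, 5:15] = True
        contours = extract_slice_contours(slice_mask(sq), 1)
        assert len(contours) == 1
        assert abs(abs(contours[0].area()) - sq.sum()) <= 1.0 + sq.sum() * 0.1

    def test_empty_slice_no_contours(self):
        assert extract_slice_contours(
            slice_mask(np.zeros((10, 10), dtype=bool)), 1) == []

    def test_two_blobs_two_contours(self):
        two = np.zeros((30, 30), dtype=bool)
        two[2:8, 2:8] = True
        two[20:26, 20:26] = True
        assert len(extract_slice_contours(slice_mask(two), 1)) == 2

    def test_absent_label_empty_list(self):
        sq = np.zeros((10, 10), dtype=bool)
        sq[2:6, 2:6] = True
        assert extract_slice_contours(slice_mask(sq), 9) == []

    def test_counterclockwise(self):
        sq = np.zeros((20, 20), dtype=bool)
        sq[5:15, 5:15] = True
        assert extract_slice_contours(slice_mask(sq), 1)[0].area() > 0


class TestInfluence:
    def test_collinear_point_scores_zero(self):
        pts = np.array([[0, 0], [0, 5], [0, 10], [10, 10], [10, 0]], float)
        assert point_influence(SliceContour(0, pts))[1] == 0.0

    def test_corners_outrank_midpoints(self):
        # square with edge midpoints: all 8 scores evaluated exhaustively
        pts = np.array([[0, 0], [0, 5], [0, 10], [5, 10], [10, 10],
                        [10, 5], [10, 0], [5, 0]], float)
        k = point_influence(SliceContour(0, pts))
        corners, mids = k[::2], k[1::2]
        assert corners.min() > mids.max()

    def test_scaling_doubles_influence(self):
        pts = np.array([[0, 0], [1, 4], [5, 6], [7, 2], [4, -1]], float)
        k1 = point_influence(SliceContour(0, pts))
        k2 = point_influence(SliceContour(0, 2 * pts))
        assert np.allclose(k2, 2 * k1)

    def test_duplicate_points_rejected(self):
        pts = np.array([[0, 0], [0, 0], [5, 5], [0, 5]], float)
        with pytest.raises(ValueError, match="duplicate"):
            point_influence(SliceContour(0, pts))


class TestSimplify:
    def test_default_keeps_twenty_percent(self):
        assert len(simplify_contour(circle_contour(100))) == 20

    def test_subset_of_input(self):
        c = circle_contour(80)
        s = simplify_contour(c, 25)
        original = {tuple(p) for p in c.points}
        assert all(tuple(p) in original for p in s.points)

    def test_square_corners_survive(self):
        pts = []
        corners = [(0, 0), (0, 24), (24, 24), (24, 0)]
        for a, b in zip(corners, corners[1:] + corners[:1]):
            for t in np.linspace(0, 1, 26)[:-1]:
                pts.append((a[0] + t * (b[0] - a[0]), a[1] + t * (b[1] - a[1])))
        s = simplify_contour(SliceContour(0, np.array(pts)), 4)
        assert {tuple(p) for p in s.points} == {(float(r), float(c))
                                               for r, c in corners}

    def test_too_aggressive_percent_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            simplify_contour(circle_contour(100), 1)

    def test_area_loss_small_on_smooth_contours(self):
        for n, r in [(100, 20.0), (200, 25.0)]:
            c = circle_contour(n, r)
            s = simplify_contour(c, 20)
            assert abs(s.area() - c.area()) / abs(c.area()) < 0.02

    @settings(max_examples=25, deadline=None)
    @given(st.sets(st.integers(0, 119), min_size=12, max_size=40))
    def test_no_self_intersection_on_convex_inputs(self, ticks):
        th = np.sort(np.asarray(sorted(ticks))) * (2 * np.pi / 120)
        pts = np.column_stack([50 + 30 * np.cos(th), 50 + 30 * np.sin(th)])
        s = simplify_contour(SliceContour(0, pts), 40)
        assert s.is_simple()


class TestRefine:
    def test_identity_without_edits(self):
        c = circle_contour(100)
        assert np.array_equal(refine_contour(c, 20).points,
                              simplify_contour(c, 20).points)

    def test_moved_point_survives_exactly(self):
        c = circle_contour(100)
        moved = np.array([60.0, 32.0])
        c.points[0] = moved
        c.flags[0] = "user-moved"
        ref = refine_contour(c, 30)
        assert any(np.array_equal(p, moved) for p in ref.points)

    def test_deviation_localized_to_edited_span(self):
        c = circle_contour(120, r=20.0)
        center = np.array([32.0, 32.0])
        for i in (10, 11, 12):
            c.points[i] = center + (c.points[i] - center) * 1.3
            c.flags[i] = "user-moved"
        ref = refine_contour(c, 100)
        radii = np.linalg.norm(ref.points - center, axis=1)
        angles = np.arctan2(ref.points[:, 1] - center[1],
                            ref.points[:, 0] - center[0]) % (2 * np.pi)
        edited_lo, edited_hi = 2 * np.pi * 8 / 120, 2 * np.pi * 15 / 120
        outside = (angles < edited_lo) | (angles > edited_hi)
        assert np.all(np.abs(radii[outside] - 20.0) < 1.0)

    def test_roundtrip_stability(self):
        sq = np.zeros((40, 40), dtype=bool)
        rr, cc = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        sq = ((rr - 20.0) ** 2 + (cc - 20.0) ** 2) <= 12 ** 2
        mask = slice_mask(sq)
        first = extract_slice_contours(mask, 1)
        m2 = rasterize_contours(first, mask.shape, {1: "tumor"})
        second = extract_slice_contours(m2, 1)
        d1 = np.sort(np.linalg.norm(first[0].points[:, None]
                                    - second[0].points[None], axis=2).min(axis=1))
        assert d1.max() <= 1.0


class TestRasterize:
    def test_roundtrip_dice_on_blob(self):
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        blob = (((rr - 32) / 20.0) ** 2 + ((cc - 30) / 14.0) ** 2) <= 1
        mask = slice_mask(blob)
        contours = extract_slice_contours(mask, 1)
        back = rasterize_contours(contours, mask.shape, {1: "tumor"})
        assert dice(back.labels[:, :, 1] > 0, blob) >= 0.99

    def test_square_fill_count(self):
        c = SliceContour(0, np.array([[0, 0], [0, 9], [9, 9], [9, 0]], float))
        m = rasterize_contours([c], (20, 20, 3))
        assert abs(int((m.labels[:, :, 0] > 0).sum()) - 100) <= 4

    def test_empty_list_empty_mask(self):
        m = rasterize_contours([], (10, 10, 3))
        assert not m.labels.any()

    def test_self_intersection_rejected(self):
        bow = SliceContour(3, np.array([[0, 0], [10, 10], [0, 10], [10, 0]], float))
        with pytest.raises(ValueError, match="slice 3"):
            rasterize_contours([bow], (20, 20, 5))


class TestManualIngest:
    def test_triangle(self):
        data = {"object_id": "tumor", "label": 3,
                "slices": [{"index": 2, "points": [[1, 1], [1, 8], [8, 4]]}]}
        cs = manual_contour_ingest(data)
        assert len(cs) == 1 and len(cs[0]) == 3
        assert all(f == "user-drawn" for f in cs[0].flags)

    def test_degenerate_rejected(self):
        data = {"object_id": "x", "label": 1,
                "slices": [{"index": 0, "points": [[1, 1], [5, 5]]}]}
        with pytest.raises(ValueError, match="3 points"):
            manual_contour_ingest(data)

    def test_tumor_spans_drawn_slices(self):
        tri = [[10, 10], [10, 30], [30, 20]]
        data = {"object_id": "tumor", "label": 3,
                "slices": [{"index": k, "points": tri} for k in (4, 5, 6)]}
        cs = manual_contour_ingest(data)
        m = rasterize_contours(cs, (40, 40, 12), {3: "tumor"})
        filled = sorted(set(np.nonzero(m.labels)[2]))
        assert filled == [4, 5, 6]

    def test_json_file_input(self, tmp_path):
        p = tmp_path / "c.json"
        p.write_text(json.dumps({"object_id": "t", "label": 1, "slices": [
            {"index": 0, "points": [[0, 0], [0, 5], [5, 5], [5, 0]]}]}))
        assert len(manual_contour_ingest(str(p))) == 1


class TestEdits:
    def test_move_point_edit(self):
        c = circle_contour(40)
        out = apply_edits([c], [ContourEdit(0, "", "move_point",
                                            point_index=3, new_point=(99.0, 99.0))])
        assert np.array_equal(out[0].points[3], [99.0, 99.0])
        assert out[0].flags[3] == "user-moved"

    def test_delete_object(self):
        c = circle_contour(40)
        assert apply_edits([c], [ContourEdit(0, "", "delete_object")]) == []

    def test_bad_index_rejected(self):
        c = circle_contour(40)
        with pytest.raises(IndexError):
            apply_edits([c], [ContourEdit(0, "", "move_point",
                                          point_index=400, new_point=(0, 0))])
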