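import json
import warnings

import numpy as np
import pytest

from patic.geometry import Contour, area, perimeter
from patic.minkowski import qp_spectrum, qp_thetap
from patic.shapes_io import (
    LabelField,
    extract_contours,
    polygonalize,
    read_labels,
    read_polygons,
    write_measures,
    write_polygons,
)
from patic.synth import TissueFrame, rasterize, voronoi_tissue


def disk_labels(radius_px=50, pad=6):
    n = 2 * (radius_px + pad)
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2
    return (( (xx + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2) < radius_px**2).astype(np.int32)


class TestLabelField:
    def test_float_labels_rejected(self):
        with pytest.raises(ValueError, match="integers"):
            LabelField(np.ones((4, 4), dtype=float))

    def test_negative_labels_rejected(self):
        with pytest.raises(ValueError):
            LabelField(np.full((4, 4), -1))

    def test_multi_component_label_pruned_with_warning(self):
        arr = np.zeros((6, 6), dtype=np.int32)
        arr[0:2, 0:2] = 1
        arr[4:6, 4:5] = 1  # disconnected fragment, smaller
        with pytest.warns(UserWarning, match="components"):
            clean = LabelField(arr).validate_connectivity()
        assert (clean.data == 1).sum() == 4


class TestReadLabels:
    def test_multipage_tiff_roundtrip(self, tmp_path):
        import tifffile

        stack = np.stack([np.full((5, 7), k + 1, dtype=np.uint16) for k in range(3)])
        path = tmp_path / "stack.tiff"
        tifffile.imwrite(path, stack, photometric="minisblack")
        fields = read_labels(path)
        assert len(fields) == 3
        assert fields[2].frame == 2
        np.testing.assert_array_equal(fields[1].data, stack[1])

    def test_grayscale_png(self, tmp_path):
        import imageio.v3 as iio

        arr = np.zeros((8, 8), dtype=np.uint8)
        arr[2:6, 2:6] = 3
        path = tmp_path / "labels.png"
        iio.imwrite(path, arr)
        (field,) = read_labels(path)
        assert set(field.labels()) == {3}

    def test_rgb_png_rejected(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "rgb.png"
        iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="single-channel"):
            read_labels(path)


class TestExtractContours:
    def test_filled_rectangle_pixel_boundary(self):
        arr = np.zeros((9, 14), dtype=np.int32)
        arr[2:7, 3:13] = 1  # 10 x 5 pixel rectangle
        frame = extract_contours(LabelField(arr), exclude_boundary=False)
        (c,) = frame.contours
        assert area(c) == pytest.approx(50.0, abs=1e-12)
        assert perimeter(c) == pytest.approx(30.0, abs=1e-12)
        assert c.n_vertices == 4

    def test_single_pixel_is_unit_square(self):
        arr = np.zeros((4, 4), dtype=np.int32)
        arr[1, 2] = 7
        frame = extract_contours(LabelField(arr), exclude_boundary=False)
        (c,) = frame.contours
        assert area(c) == pytest.approx(1.0)
        assert perimeter(c) == pytest.approx(4.0)

    def test_area_equals_pixel_count_on_tissue(self):
        f = voronoi_tissue(12, box=(4, 4), seed=9, periodic=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            field = LabelField(rasterize(f, 20)).validate_connectivity()
        frame = extract_contours(field, exclude_boundary=False)
        for c in frame.contours:
            assert area(c) == pytest.approx(float((field.data == c.cell_id).sum()),
                                            rel=1e-12)

    def test_boundary_cells_dropped_by_default(self):
        arr = np.zeros((6, 6), dtype=np.int32)
        arr[0:3, 0:3] = 1  # touches border
        arr[3:5, 3:5] = 2  # interior
        frame = extract_contours(LabelField(arr))
        assert [c.cell_id for c in frame.contours] == [2]

    def test_smoothed_disk_has_low_spurious_order(self):
        """An unsmoothed pixel staircase inflates 4-atic order; a moving
        average restores the circle's isotropy."""
        field = LabelField(disk_labels(50))
        rough = extract_contours(field, exclude_boundary=False)
        smooth = extract_contours(field, smoothing_window=7, exclude_boundary=False)
        q4_rough = qp_thetap(rough.contours[0], 4)[0]
        spec = qp_spectrum(smooth.contours[0], 6)
        assert q4_rough > 0.2  # staircase artifact
        for p in range(1, 7):
            assert spec[p][0] < 0.02

    def test_smoothing_stays_near_traced_contour(self):
        field = LabelField(disk_labels(20))
        rough = extract_contours(field, exclude_boundary=False).contours[0]
        smooth = extract_contours(field, smoothing_window=9,
                                  exclude_boundary=False).contours[0]
        # Hausdorff-type bound: each smoothed vertex within window/2 px
        from scipy.spatial import cKDTree

        d, _ = cKDTree(rough.vertices).query(smooth.vertices)
        assert d.max() <= 9 / 2
        assert area(smooth) > 0  # winding preserved (still CCW)

    def test_empty_label_field_rejected(self):
        with pytest.raises(ValueError):
            extract_contours(LabelField(np.zeros((4, 4), dtype=np.int32)))


class TestPolygonalize:
    def test_voronoi_junctions_near_true_vertices(self):
        f = voronoi_tissue(20, box=(5, 5), seed=13, periodic=False)
        ppu = 40
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            field = LabelField(rasterize(f, ppu), pixel_size=1 / ppu).validate_connectivity()
        poly = polygonalize(field, exclude_boundary=True)
        true_vertices = np.concatenate([c.vertices for c in f.contours])
        for c in poly.contours:
            for v in c.vertices:
                d = np.linalg.norm(true_vertices - v, axis=1).min()
                assert d <= 1.5 / ppu

    def test_polygons_raise_hexatic_order_vs_smoothed(self):
        """Vertex polygons of a hexagonal-ish tissue score higher q_6 than
        the smoothed contours of the same cells."""
        f = voronoi_tissue(36, box=(6, 6), seed=3, periodic=True, lloyd_iterations=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            field = LabelField(rasterize(f, 20)).validate_connectivity()
        poly = polygonalize(field)
        smooth = extract_contours(field, smoothing_window=7)
        common = set(c.cell_id for c in poly.contours) & set(
            c.cell_id for c in smooth.contours)
        q6p = np.mean([qp_thetap(c, 6)[0] for c in poly.contours if c.cell_id in common])
        q6s = np.mean([qp_thetap(c, 6)[0] for c in smooth.contours if c.cell_id in common])
        assert q6p > q6s

    def test_isolated_blob_falls_back_with_warning(self):
        arr = np.zeros((8, 8), dtype=np.int32)
        arr[2:6, 2:6] = 1
        with pytest.warns(UserWarning, match="junction"):
            frame = polygonalize(LabelField(arr), exclude_boundary=False)
        assert area(frame.contours[0]) == pytest.approx(16.0)


class TestPolygonFiles:
    def test_json_roundtrip(self, tmp_path):
        tri = Contour([(0, 0), (2, 0), (1, 1.5)], cell_id=4, frame=0)
        frame = TissueFrame(frame=0, contours=[tri], box=(3, 3), periodic=False)
        path = tmp_path / "cells.json"
        write_polygons([frame], path)
        (back,) = read_polygons(path)
        assert back.contours[0].cell_id == 4
        np.testing.assert_allclose(back.contours[0].vertices, tri.vertices)

    def test_csv_long_format(self, tmp_path):
        rows = ["frame,cell_id,vertex_index,x,y"]
        for fr in (0, 1):
            for cid in range(3):
                for k, (x, y) in enumerate([(0, 0), (1, 0), (0.5, 1)]):
                    rows.append(f"{fr},{cid},{k},{x + 2 * cid},{y + fr}")
        path = tmp_path / "cells.csv"
        path.write_text("\n".join(rows))
        frames = read_polygons(path)
        assert len(frames) == 2
        assert frames[1].n_cells == 3

    def test_clockwise_input_normalized(self, tmp_path):
        payload = {"frames": [{"frame": 0, "box": None, "periodic": False,
                               "cells": [{"id": 1, "vertices": [[0, 0], [0, 1], [1, 1], [1, 0]]}]}]}
        path = tmp_path / "cw.json"
        path.write_text(json.dumps(payload))
        (frame,) = read_polygons(path)
        assert area(frame.contours[0]) == pytest.approx(1.0)

    def test_open_polygon_rejected(self, tmp_path):
        payload = {"frames": [{"frame": 0, "cells": [{"id": 1, "vertices": [[0, 0], [1, 0]]}]}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="cell 1"):
            read_polygons(path)

    def test_duplicate_cell_ids_rejected(self, tmp_path):
        cell = {"id": 1, "vertices": [[0, 0], [1, 0], [0.5, 1]]}
        payload = {"frames": [{"frame": 0, "cells": [cell, cell]}]}
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="duplicate"):
            read_polygons(path)


class TestWriteMeasures:
    def test_full_precision_roundtrip(self, tmp_path):
        import pandas as pd

        from patic.minkowski import measure_frame

        f = voronoi_tissue(10, box=(4, 4), seed=2, periodic=True)
        records = measure_frame(f)
        path = tmp_path / "measures.csv"
        write_measures(records, path)
        df = pd.read_csv(path, float_precision="round_trip")
        assert len(df) == 10
        r0 = records[0]
        row = df[df.cell_id == r0.cell_id].iloc[0]
        assert row["q_6"] == r0.qp[6]  # exact repr round-trip
        assert row["theta_6"] == r0.thetap[6]

    def test_empty_records_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_measures([], path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 1
        assert text[0].startswith("frame,cell_id")
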