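"""Cell taxonomy, polygon geometry, region splitting, and annotation I/O."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteoquant.annotation import (
    AnnotationError,
    CellType,
    Polygon,
    classify_cell_type,
    labelme_to_region,
    polygon_area,
    polygon_bbox,
    read_region_annotation,
    read_well_annotation,
    region_to_labelme,
    split_well_into_regions,
    tightest_square_bbox,
    write_well_annotation,
)
from conftest import random_simple_polygon


class TestClassifyCellType:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (1, CellType.PREOSTEOCLAST),
            (2, CellType.PREOSTEOCLAST),
            (3, CellType.OSTEOCLAST_I),
            (7, CellType.OSTEOCLAST_I),
            (14, CellType.OSTEOCLAST_I),
            (15, CellType.OSTEOCLAST_II),
            (40, CellType.OSTEOCLAST_II),
        ],
    )
    def test_nucleus_count_boundaries(self, n, expected):
        assert classify_cell_type(n) is expected

    def test_ghost_flag_dominates(self):
        assert classify_cell_type(7, is_ghost=True) is CellType.GHOST

    def test_anucleate_trap_positive_is_invalid(self):
        with pytest.raises(AnnotationError):
            classify_cell_type(0, is_ghost=False)

    def test_preimages_partition_positive_integers(self):
        """Every nucleus count maps to exactly one TRAP+ class, in
        nondecreasing class order."""
        classes = [classify_cell_type(n) for n in range(1, 60)]
        assert set(classes) == {
            CellType.PREOSTEOCLAST,
            CellType.OSTEOCLAST_I,
            CellType.OSTEOCLAST_II,
        }
        order = [CellType.PREOSTEOCLAST, CellType.OSTEOCLAST_I, CellType.OSTEOCLAST_II]
        ranks = [order.index(c) for c in classes]
        assert ranks == sorted(ranks)


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])) == 1.0

    def test_triangle(self):
        assert polygon_area(Polygon([(0, 0), (4, 0), (0, 3)])) == 6.0

    def test_orientation_and_rotation_invariance(self, rng):
        poly = random_simple_polygon(rng)
        verts = list(poly.vertices)
        a = polygon_area(poly)
        assert polygon_area(Polygon(verts[::-1])) == pytest.approx(a)
        assert polygon_area(Polygon(verts[3:] + verts[:3])) == pytest.approx(a)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(AnnotationError):
            Polygon([(0, 0), (1, 1)])

    def test_matches_monte_carlo_estimate(self, rng):
        """Shoelace area of a random simple 12-gon agrees with rejection
        sampling to within 1%."""
        poly = random_simple_polygon(rng, n=12)
        x0, y0, x1, y1 = poly.bounds
        n = 1_000_000
        pts_x = rng.uniform(x0, x1, size=n)
        pts_y = rng.uniform(y0, y1, size=n)
        import shapely

        frac = shapely.contains_xy(poly.to_shapely(), pts_x, pts_y).mean()
        mc_area = frac * (x1 - x0) * (y1 - y0)
        assert polygon_area(poly) == pytest.approx(mc_area, rel=0.01)


class TestTightestSquareBBox:
    def test_wide_extent_becomes_square(self):
        poly = Polygon([(10, 10), (30, 10), (30, 20), (10, 20)])
        box = tightest_square_bbox(poly, 1000, 1000)
        assert box.width == box.height == 20
        assert (box.x_min, box.y_min, box.x_max, box.y_max) == (10, 5, 30, 25)

    def test_square_polygon_is_its_own_bbox(self, square_polygon):
        poly = Polygon([(10, 10), (30, 10), (30, 30), (10, 30)])
        box = tightest_square_bbox(poly, 100, 100)
        assert (box.x_min, box.y_min, box.x_max, box.y_max) == (10, 10, 30, 30)

    def test_shifted_not_shrunk_at_border(self):
        poly = Polygon([(0, 0), (20, 0), (20, 10), (0, 10)])
        box = tightest_square_bbox(poly, 1000, 1000)
        assert box.width == box.height == 20
        assert box.y_min == 0  # shifted to stay inside

    def test_clip_when_side_exceeds_image(self):
        # taller than the image is wide: squareness yields to containment
        poly = Polygon([(1, 5), (7, 5), (7, 90), (1, 90)])
        box = tightest_square_bbox(poly, 10, 100)
        assert box.x_min >= 0 and box.x_max <= 10
        x0, y0, x1, y1 = poly.bounds
        assert box.x_min <= x0 and box.x_max >= x1
        assert box.y_min <= y0 and box.y_max >= y1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_containment_and_minimality(self, seed):
        """The square contains every vertex and no smaller integer-sided
        square could (side >= max extent, within an interior image)."""
        r = np.random.default_rng(seed)
        poly = random_simple_polygon(r, n=int(r.integers(3, 15)),
                                     cx=500, cy=500, r=float(r.uniform(5, 80)))
        box = tightest_square_bbox(poly, 1000, 1000)
        x0, y0, x1, y1 = poly.bounds
        assert box.width == pytest.approx(box.height)
        assert box.x_min <= x0 and box.x_max >= x1
        assert box.y_min <= y0 and box.y_max >= y1
        assert box.width >= max(x1 - x0, y1 - y0)
        assert box.width <= np.ceil(max(x1 - x0, y1 - y0)) + 1e-6
        pb = polygon_bbox(poly)
        assert box.x_min <= pb.x_min and box.x_max >= pb.x_max


class TestSplitWellIntoRegions:
    def test_divides_1000px_well_into_16_regions(self):
        image = np.zeros((1000, 1000, 3), dtype=np.uint8)
        regions = split_well_into_regions(image)
        assert len(regions) == 16
        assert all(r.shape == (250, 250, 3) for r, _off in regions)

    def test_identity_grid(self):
        image = np.arange(36, dtype=np.uint8).reshape(6, 6)
        [(crop, off)] = split_well_into_regions(image, 1, 1)
        assert off == (0, 0)
        np.testing.assert_array_equal(crop, image)

    def test_remainder_goes_to_last_column_and_coverage_is_exact(self):
        image = np.zeros((1000, 1001), dtype=np.uint8)
        regions = split_well_into_regions(image, 4, 4)
        count = np.zeros_like(image, dtype=int)
        widths = set()
        for crop, (x, y) in regions:
            h, w = crop.shape
            count[y : y + h, x : x + w] += 1
            if x == max(off[0] for _c, off in regions):
                widths.add(w)
        assert widths == {251}
        assert (count == 1).all()

    def test_reassembly_is_pixel_exact(self, rng):
        image = rng.integers(0, 255, size=(97, 113, 3), dtype=np.uint8)
        out = np.zeros_like(image)
        for crop, (x, y) in split_well_into_regions(image, 4, 4):
            out[y : y + crop.shape[0], x : x + crop.shape[1]] = crop
        np.testing.assert_array_equal(out, image)

    def test_grid_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            split_well_into_regions(np.zeros((3, 3)), 4, 4)


class TestAnnotationIO:
    def test_single_polygon_read(self, tmp_path):
        data = {
            "imagePath": "r.png",
            "imageWidth": 100,
            "imageHeight": 100,
            "shapes": [
                {
                    "label": "osteoclast_type1",
                    "points": [[10, 10], [40, 12], [38, 40], [8, 35], [9, 20]],
                    "shape_type": "polygon",
                }
            ],
        }
        path = tmp_path / "r.json"
        path.write_text(json.dumps(data))
        region = read_region_annotation(path)
        assert len(region.cells) == 1
        assert region.cells[0].cell_type is CellType.OSTEOCLAST_I

    def test_unknown_label_reported(self, tmp_path):
        data = {
            "imagePath": "r.png",
            "imageWidth": 100,
            "imageHeight": 100,
            "shapes": [
                {"label": "unknown_cell", "points": [[1, 1], [5, 1], [3, 6]],
                 "shape_type": "polygon"}
            ],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(data))
        with pytest.raises(AnnotationError, match="unknown_cell"):
            read_region_annotation(path)

    def test_out_of_bounds_vertices_name_shape_index(self):
        data = {
            "imagePath": "r.png",
            "imageWidth": 10,
            "imageHeight": 10,
            "shapes": [
                {"label": "ghost", "points": [[1, 1], [50, 1], [3, 6]],
                 "shape_type": "polygon"}
            ],
        }
        with pytest.raises(AnnotationError, match="shape 0"):
            labelme_to_region(data)

    def test_malformed_json(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(AnnotationError, match="malformed"):
            read_region_annotation(path)

    def test_well_round_trip_is_lossless(self, tmp_path, tiny_well):
        paths = write_well_annotation(tmp_path, tiny_well)
        assert len(paths) == 4
        back = read_well_annotation(paths)
        assert back.well_id == tiny_well.well_id
        assert back.width == tiny_well.width and back.height == tiny_well.height
        for orig, rt in zip(tiny_well.regions, back.regions):
            assert rt.offset == orig.offset
            assert len(rt.cells) == len(orig.cells)
            for c0, c1 in zip(orig.cells, rt.cells):
                assert c1.cell_type is c0.cell_type
                assert c1.n_nuclei == c0.n_nuclei
                np.testing.assert_allclose(
                    c1.polygon.as_array(), c0.polygon.as_array()
                )
        # and the writer emits the documented dialect
        doc = json.loads(open(paths[0]).read())
        assert {"imagePath", "imageWidth", "imageHeight", "shapes"} <= set(doc)

    def test_labelme_round_trip_dict_level(self, tiny_well):
        region = tiny_well.regions[1]
        doc = region_to_labelme(region, "img.png", "w1")
        back = labelme_to_region(doc)
        assert back.region_id == region.region_id
        assert back.cells[0].n_nuclei == region.cells[0].n_nuclei
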