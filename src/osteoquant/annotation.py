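"""Domain model for annotated osteoclast cultures.

A culture well is imaged as one large RGB micrograph; human annotators (or
the synthetic generator) outline each cell with a polygon and assign one of
four morphological types.  Wells are partitioned into a grid of equally
sized regions which are annotated as separate images; region-local polygon
coordinates plus the region offset recover well coordinates.

Coordinate conventions, used everywhere in this package:

* pixels are 0-based, origin at the top-left, x rightwards, y downwards;
* bounding boxes are half-open: pixel column ``x`` belongs to a box iff
  ``x_min <= x < x_max`` (idem for rows), so a box's pixel width is
  ``x_max - x_min``.
"""

from __future__ import annotations

import enum
import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon


class AnnotationError(ValueError):
    """Raised for invalid annotations (bad nucleus counts, degenerate
    polygons, malformed annotation files)."""


class CellType(enum.Enum):
    """The four morphological cell types of a TRAP-stained culture.

    The three TRAP+ classes are ordered by minimum nucleus count:
    preosteoclasts (1-2 nuclei) < type I osteoclasts (3-14) < type II
    osteoclasts (>= 15).  Ghost cells are vanished cells recognisable only
    by their faint silhouette; they carry no nucleus count.
    """

    PREOSTEOCLAST = "preosteoclast"
    OSTEOCLAST_I = "osteoclast_type1"
    OSTEOCLAST_II = "osteoclast_type2"
    GHOST = "ghost"

    @property
    def min_nuclei(self) -> int | None:
        return {
            CellType.PREOSTEOCLAST: 1,
            CellType.OSTEOCLAST_I: 3,
            CellType.OSTEOCLAST_II: 15,
        }.get(self)


#: TRAP+ classes in nucleus-count order (excludes GHOST).
TRAP_POSITIVE = (CellType.PREOSTEOCLAST, CellType.OSTEOCLAST_I, CellType.OSTEOCLAST_II)

#: Default mapping from annotation-file label strings to cell types.  The
#: keys cover the label dialects we emit and common free-text variants;
#: extend via the ``label_map`` argument of :func:`read_region_annotation`.
DEFAULT_LABEL_MAP: dict[str, CellType] = {
    "preosteoclast": CellType.PREOSTEOCLAST,
    "pre": CellType.PREOSTEOCLAST,
    "osteoclast_type1": CellType.OSTEOCLAST_I,
    "osteoclast_type_1": CellType.OSTEOCLAST_I,
    "type1": CellType.OSTEOCLAST_I,
    "osteoclast_i": CellType.OSTEOCLAST_I,
    "osteoclast_type2": CellType.OSTEOCLAST_II,
    "osteoclast_type_2": CellType.OSTEOCLAST_II,
    "type2": CellType.OSTEOCLAST_II,
    "osteoclast_ii": CellType.OSTEOCLAST_II,
    "ghost": CellType.GHOST,
    "ghost_cell": CellType.GHOST,
}


def classify_cell_type(n_nuclei: int, is_ghost: bool = False) -> CellType:
    """Map a nucleus count (and the ghost flag) to a cell type.

    Preosteoclasts are TRAP+ cells with 1-2 nuclei; type I osteoclasts have
    3-14 nuclei; type II osteoclasts have 15 or more.  The ghost flag
    dominates: a vanished cell is GHOST regardless of any nucleus count the
    annotator may have recorded.

    Raises
    ------
    AnnotationError
        If ``n_nuclei`` is 0 (or negative) for a non-ghost cell: there is
        no anucleate TRAP+ cell.
    """
    if is_ghost:
        return CellType.GHOST
    if n_nuclei < 1:
        raise AnnotationError(
            f"a TRAP+ cell must have at least one nucleus, got {n_nuclei}"
        )
    if n_nuclei <= 2:
        return CellType.PREOSTEOCLAST
    if n_nuclei < 15:
        return CellType.OSTEOCLAST_I
    return CellType.OSTEOCLAST_II


@dataclass(frozen=True)
class BBox:
    """Axis-aligned half-open pixel box."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def shift(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def intersection(self, other: "BBox") -> "BBox | None":
        x0 = max(self.x_min, other.x_min)
        y0 = max(self.y_min, other.y_min)
        x1 = min(self.x_max, other.x_max)
        y1 = min(self.y_max, other.y_max)
        if x0 < x1 and y0 < y1:
            return BBox(x0, y0, x1, y1)
        return None


@dataclass(frozen=True)
class Polygon:
    """A simple polygon outlining one cell, as an ordered vertex list."""

    vertices: tuple[tuple[float, float], ...]

    def __init__(self, vertices: Iterable[Sequence[float]]):
        verts = tuple((float(x), float(y)) for x, y in vertices)
        if len(verts) < 3:
            raise AnnotationError(
                f"polygon needs at least 3 vertices, got {len(verts)}"
            )
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        a = self.as_array()
        return (a[:, 0].min(), a[:, 1].min(), a[:, 0].max(), a[:, 1].max())

    def shift(self, dx: float, dy: float) -> "Polygon":
        return Polygon([(x + dx, y + dy) for x, y in self.vertices])


def polygon_area(polygon: Polygon) -> float:
    """Absolute (shoelace) area of a polygon in px².

    Invariant under vertex rotation and orientation reversal; degenerate
    (zero-area) vertex lists return 0.
    """
    return float(polygon.to_shapely().area)


def polygon_bbox(polygon: Polygon) -> BBox:
    x0, y0, x1, y1 = polygon.bounds
    # guard against degenerate extent: a box must have positive size
    if x1 <= x0:
        x1 = x0 + 1.0
    if y1 <= y0:
        y1 = y0 + 1.0
    return BBox(x0, y0, x1, y1)


def tightest_square_bbox(
    polygon: Polygon, image_w: float | None = None, image_h: float | None = None
) -> BBox:
    """The tightest square box containing the whole cell polygon.

    Detection pipelines work on bounding boxes, so each annotated polygon is
    converted to the tightest square containing the entire cell: side equal
    to the larger of the polygon's axis-aligned width and height (rounded up
    to an integer), centred on the polygon's extent.  Near the image border
    the square is shifted -- not shrunk -- to fit; squareness yields to
    containment only when the side exceeds an image dimension, in which case
    that axis is clipped to the image.
    """
    x0, y0, x1, y1 = polygon.bounds
    side = math.ceil(max(x1 - x0, y1 - y0))
    side = max(side, 1)
    cx = (x0 + x1) / 2.0
    cy = (y0 + y1) / 2.0

    def _axis(lo_c: float, dim: float | None) -> tuple[float, float]:
        lo = lo_c - side / 2.0
        hi = lo + side
        if dim is None:
            return lo, hi
        if side > dim:
            return 0.0, float(dim)  # squareness yields to containment
        if lo < 0:
            lo, hi = 0.0, float(side)
        elif hi > dim:
            lo, hi = float(dim) - side, float(dim)
        return lo, hi

    bx0, bx1 = _axis(cx, image_w)
    by0, by1 = _axis(cy, image_h)
    return BBox(bx0, by0, bx1, by1)


@dataclass(frozen=True)
class CellAnnotation:
    """One annotated cell: outline polygon, type, and (for TRAP+ cells)
    the nucleus count the annotator observed."""

    polygon: Polygon
    cell_type: CellType
    n_nuclei: int | None = None

    def __post_init__(self) -> None:
        if self.n_nuclei is None:
            if self.cell_type is not CellType.GHOST:
                # TRAP+ annotations without counts are legal (human files
                # rarely record them) but must not contradict the taxonomy.
                return
        else:
            if self.cell_type is not CellType.GHOST:
                expected = classify_cell_type(self.n_nuclei, False)
                if expected is not self.cell_type:
                    raise AnnotationError(
                        f"{self.n_nuclei} nuclei imply {expected.value}, "
                        f"annotation says {self.cell_type.value}"
                    )


@dataclass(frozen=True)
class RegionAnnotation:
    """Annotations of one region of a well, in region-local coordinates."""

    region_id: int
    offset: tuple[int, int]
    width: int
    height: int
    cells: tuple[CellAnnotation, ...] = ()

    def __post_init__(self) -> None:
        for i, cell in enumerate(self.cells):
            x0, y0, x1, y1 = cell.polygon.bounds
            if x0 < 0 or y0 < 0 or x1 > self.width or y1 > self.height:
                raise AnnotationError(
                    f"cell {i} polygon {cell.polygon.bounds} exceeds region "
                    f"{self.width}x{self.height}"
                )


@dataclass(frozen=True)
class WellAnnotation:
    """A full annotated culture well: image reference plus a disjoint,
    covering set of annotated regions."""

    well_id: str
    image_path: str
    width: int
    height: int
    regions: tuple[RegionAnnotation, ...] = ()

    def __post_init__(self) -> None:
        covered = 0
        for r in self.regions:
            ox, oy = r.offset
            if ox < 0 or oy < 0 or ox + r.width > self.width or oy + r.height > self.height:
                raise AnnotationError(f"region {r.region_id} exceeds well bounds")
            covered += r.width * r.height
        if self.regions and covered != self.width * self.height:
            raise AnnotationError(
                "regions do not tile the well exactly "
                f"({covered} px² covered of {self.width * self.height})"
            )
        # pairwise disjointness follows from exact coverage + bounds when
        # offsets are distinct; verify offsets are unique to be safe.
        offsets = [r.offset for r in self.regions]
        if len(set(offsets)) != len(offsets):
            raise AnnotationError("duplicate region offsets")

    def iter_cells_well_coords(self):
        """Yield ``(CellAnnotation, region_id)`` with polygons shifted to
        well coordinates."""
        for r in self.regions:
            ox, oy = r.offset
            for cell in r.cells:
                yield replace(cell, polygon=cell.polygon.shift(ox, oy)), r.region_id

    def all_cells(self) -> list[CellAnnotation]:
        return [c for c, _ in self.iter_cells_well_coords()]


# ---------------------------------------------------------------------------
# Region splitting


def region_grid(
    width: int, height: int, grid_rows: int = 4, grid_cols: int = 4
) -> list[tuple[int, int, int, int]]:
    """Rectangles ``(x, y, w, h)`` of a rows×cols partition, row-major.

    Remainder pixels of non-divisible dimensions go to the last row/column,
    so the rectangles are disjoint and cover every pixel exactly once.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid must be at least 1x1")
    if grid_cols > width or grid_rows > height:
        raise ValueError(
            f"grid {grid_rows}x{grid_cols} larger than image {width}x{height} px"
        )
    base_w = width // grid_cols
    base_h = height // grid_rows
    rects = []
    for i in range(grid_rows):
        y = i * base_h
        h = base_h if i < grid_rows - 1 else height - y
        for j in range(grid_cols):
            x = j * base_w
            w = base_w if j < grid_cols - 1 else width - x
            rects.append((x, y, w, h))
    return rects


def split_well_into_regions(
    image: np.ndarray, grid_rows: int = 4, grid_cols: int = 4
) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Split a well image into a grid of region images.

    Returns row-major ``(region image, (x, y) offset)`` pairs; the default
    4×4 grid gives the 16 regions used for annotation.  Views, not copies.
    """
    h, w = image.shape[:2]
    return [
        (image[y : y + rh, x : x + rw], (x, y))
        for x, y, rw, rh in region_grid(w, h, grid_rows, grid_cols)
    ]


# ---------------------------------------------------------------------------
# Annotation file I/O (LabelMe-compatible JSON dialect)
#
# Each region is one JSON file with the standard LabelMe keys (imagePath,
# imageWidth, imageHeight, shapes[{label, points, shape_type}]) plus a
# compatible superset: wellId, regionId, regionOffset and per-shape
# n_nuclei.  A well is a set of region files sharing a wellId.

_TYPE_TO_LABEL = {
    CellType.PREOSTEOCLAST: "preosteoclast",
    CellType.OSTEOCLAST_I: "osteoclast_type1",
    CellType.OSTEOCLAST_II: "osteoclast_type2",
    CellType.GHOST: "ghost",
}


def region_to_labelme(region: RegionAnnotation, image_path: str, well_id: str) -> dict:
    shapes = []
    for cell in region.cells:
        shape = {
            "label": _TYPE_TO_LABEL[cell.cell_type],
            "points": [[x, y] for x, y in cell.polygon.vertices],
            "shape_type": "polygon",
        }
        if cell.n_nuclei is not None:
            shape["n_nuclei"] = int(cell.n_nuclei)
        shapes.append(shape)
    return {
        "imagePath": image_path,
        "imageWidth": region.width,
        "imageHeight": region.height,
        "shapes": shapes,
        "wellId": well_id,
        "regionId": region.region_id,
        "regionOffset": [region.offset[0], region.offset[1]],
    }


def labelme_to_region(
    data: dict, label_map: dict[str, CellType] | None = None
) -> RegionAnnotation:
    label_map = label_map if label_map is not None else DEFAULT_LABEL_MAP
    try:
        width = int(data["imageWidth"])
        height = int(data["imageHeight"])
        shapes = data["shapes"]
    except KeyError as exc:
        raise AnnotationError(f"missing required LabelMe key: {exc}") from None

    unknown: list[tuple[int, str]] = []
    cells: list[CellAnnotation] = []
    for idx, shape in enumerate(shapes):
        stype = shape.get("shape_type", "polygon")
        if stype != "polygon":
            raise AnnotationError(f"shape {idx}: unsupported shape_type {stype!r}")
        label = str(shape.get("label", ""))
        ctype = label_map.get(label.strip().lower())
        if ctype is None:
            unknown.append((idx, label))
            continue
        try:
            poly = Polygon(shape["points"])
        except (AnnotationError, TypeError, ValueError) as exc:
            raise AnnotationError(f"shape {idx}: invalid polygon ({exc})") from None
        x0, y0, x1, y1 = poly.bounds
        if x0 < 0 or y0 < 0 or x1 > width or y1 > height:
            raise AnnotationError(
                f"shape {idx}: vertices outside image bounds {width}x{height}"
            )
        n_nuclei = shape.get("n_nuclei")
        cells.append(
            CellAnnotation(
                polygon=poly,
                cell_type=ctype,
                n_nuclei=None if n_nuclei is None else int(n_nuclei),
            )
        )
    if unknown:
        listing = ", ".join(f"shape {i}: {lbl!r}" for i, lbl in unknown)
        raise AnnotationError(f"unknown labels in annotation file: {listing}")

    offset = tuple(data.get("regionOffset", (0, 0)))
    return RegionAnnotation(
        region_id=int(data.get("regionId", 0)),
        offset=(int(offset[0]), int(offset[1])),
        width=width,
        height=height,
        cells=tuple(cells),
    )


def write_region_annotation(
    path: str | os.PathLike,
    region: RegionAnnotation,
    image_path: str = "",
    well_id: str = "",
) -> None:
    with open(path, "w") as fh:
        json.dump(region_to_labelme(region, image_path, well_id), fh, indent=2)
        fh.write("\n")


def read_region_annotation(
    path: str | os.PathLike, label_map: dict[str, CellType] | None = None
) -> RegionAnnotation:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"{path}: malformed JSON ({exc})") from None
    return labelme_to_region(data, label_map)


def write_well_annotation(
    directory: str | os.PathLike, well: WellAnnotation
) -> list[str]:
    """Write one LabelMe-dialect JSON per region; returns the file paths."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for region in well.regions:
        fname = f"{well.well_id}_region{region.region_id:02d}.json"
        path = os.path.join(directory, fname)
        write_region_annotation(path, region, image_path=well.image_path,
                                well_id=well.well_id)
        paths.append(path)
    return paths


def read_well_annotation(
    paths: Sequence[str | os.PathLike],
    well_id: str | None = None,
    image_path: str | None = None,
    width: int | None = None,
    height: int | None = None,
    label_map: dict[str, CellType] | None = None,
) -> WellAnnotation:
    """Assemble a WellAnnotation from its region files.

    Well dimensions default to the tight bounding extent of the regions,
    which equals the image size when the regions tile the full well.
    """
    regions = []
    wid = well_id
    img = image_path
    for p in paths:
        with open(p) as fh:
            data = json.load(fh)
        region = labelme_to_region(data, label_map)
        regions.append(region)
        wid = wid or data.get("wellId")
        img = img or data.get("imagePath")
    regions.sort(key=lambda r: r.region_id)
    if width is None:
        width = max(r.offset[0] + r.width for r in regions)
    if height is None:
        height = max(r.offset[1] + r.height for r in regions)
    return WellAnnotation(
        well_id=wid or "well",
        image_path=img or "",
        width=width,
        height=height,
        regions=tuple(regions),
    )
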