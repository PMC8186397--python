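"""Quantification endpoints: per-class cell counts and covered area.

The biological readout of an osteoclastogenesis assay is the number of
cells of each type and the fraction of the culture surface they cover.
Counts are exact tallies per class.  Covered area is the area of the
geometric *union* of the cell shapes, computed by rasterization at native
resolution -- never the sum of individual areas, so a cell covered by two
boxes (a known tiling artefact) contributes once and duplicates have no
effect on the area estimate.

Annotation-side area uses the richer polygon outlines; detection-side area
uses the predicted boxes.  Reports state which basis was used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as _raster_polygon

from .annotation import (
    BBox,
    CellAnnotation,
    CellType,
    Polygon,
    TRAP_POSITIVE,
    WellAnnotation,
)
from .detector import Detection


def _item_type(item) -> CellType:
    if isinstance(item, Detection):
        return item.cell_type
    if isinstance(item, CellAnnotation):
        return item.cell_type
    return item[1]


def _item_shape(item):
    if isinstance(item, Detection):
        return item.bbox
    if isinstance(item, CellAnnotation):
        return item.polygon
    return item[0]


def count_cells(items: Iterable, cell_type: CellType) -> int:
    """Number of detections/annotations of one class.  Preosteoclasts and
    ghosts are counted separately, never pooled into osteoclast counts."""
    return sum(1 for it in items if _item_type(it) is cell_type)


def _paint(mask: np.ndarray, shape) -> None:
    h, w = mask.shape
    if isinstance(shape, BBox):
        x0 = int(np.clip(np.floor(shape.x_min), 0, w))
        y0 = int(np.clip(np.floor(shape.y_min), 0, h))
        x1 = int(np.clip(np.ceil(shape.x_max), 0, w))
        y1 = int(np.clip(np.ceil(shape.y_max), 0, h))
        mask[y0:y1, x0:x1] = True
    elif isinstance(shape, Polygon):
        arr = shape.as_array()
        rr, cc = _raster_polygon(arr[:, 1], arr[:, 0], shape=mask.shape)
        mask[rr, cc] = True
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot rasterize {type(shape).__name__}")


def coverage_mask(
    items: Iterable,
    well_w: int,
    well_h: int,
    cell_types: set[CellType] | Sequence[CellType] | None = None,
) -> np.ndarray:
    """Boolean union mask of the selected classes' shapes at native
    resolution (boxes for detections, polygons for annotations)."""
    types = set(cell_types) if cell_types is not None else set(CellType)
    mask = np.zeros((well_h, well_w), dtype=bool)
    for item in items:
        if _item_type(item) in types:
            _paint(mask, _item_shape(item))
    return mask


def covered_area(
    items: Iterable,
    well_w: int,
    well_h: int,
    cell_types: set[CellType] | Sequence[CellType] | None = None,
) -> float:
    """Union area in px² of the selected classes' shapes.

    Union semantics: adding a duplicate or a shape already contained in the
    union leaves the value unchanged.
    """
    return float(coverage_mask(items, well_w, well_h, cell_types).sum())


def summed_area(items: Iterable, cell_types=None) -> float:
    """Debug statistic: the *sum* of individual shape areas (double counts
    overlaps).  Not used for reporting."""
    types = set(cell_types) if cell_types is not None else set(CellType)
    total = 0.0
    for item in items:
        if _item_type(item) in types:
            shape = _item_shape(item)
            total += shape.area if isinstance(shape, BBox) else float(
                shape.to_shapely().area
            )
    return total


def area_fraction(covered_px2: float, well_w: int, well_h: int) -> float:
    """Covered area as a fraction of the culture area."""
    well_area = well_w * well_h
    if covered_px2 > well_area:
        raise ValueError(
            f"covered area {covered_px2} exceeds well area {well_area}; "
            "check units"
        )
    return covered_px2 / well_area


@dataclass
class QuantificationReport:
    """Counts and covered areas for one well, per class and overall."""

    well_id: str
    well_w: int
    well_h: int
    um_per_px: float
    basis: str  # "boxes" (detections) or "polygons" (annotations)
    counts: dict[CellType, int]
    areas_px2: dict[CellType, float]
    trap_positive_area_px2: float

    @property
    def areas_um2(self) -> dict[CellType, float]:
        f = self.um_per_px**2
        return {t: a * f for t, a in self.areas_px2.items()}

    @property
    def area_fractions(self) -> dict[CellType, float]:
        return {
            t: area_fraction(a, self.well_w, self.well_h)
            for t, a in self.areas_px2.items()
        }

    @property
    def trap_positive_area_fraction(self) -> float:
        return area_fraction(self.trap_positive_area_px2, self.well_w, self.well_h)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in CellType:
            rows.append(
                {
                    "well_id": self.well_id,
                    "class": t.value,
                    "count": self.counts[t],
                    "area_px2": self.areas_px2[t],
                    "area_um2": self.areas_um2[t],
                    "area_fraction": self.area_fractions[t],
                    "basis": self.basis,
                }
            )
        rows.append(
            {
                "well_id": self.well_id,
                "class": "trap_positive_total",
                "count": sum(self.counts[t] for t in TRAP_POSITIVE),
                "area_px2": self.trap_positive_area_px2,
                "area_um2": self.trap_positive_area_px2 * self.um_per_px**2,
                "area_fraction": self.trap_positive_area_fraction,
                "basis": self.basis,
            }
        )
        return pd.DataFrame(rows)


def quantify_items(
    items: Sequence,
    well_id: str,
    well_w: int,
    well_h: int,
    um_per_px: float,
    basis: str,
) -> QuantificationReport:
    counts = {t: count_cells(items, t) for t in CellType}
    areas = {t: covered_area(items, well_w, well_h, {t}) for t in CellType}
    trap_area = covered_area(items, well_w, well_h, set(TRAP_POSITIVE))
    return QuantificationReport(
        well_id=well_id,
        well_w=well_w,
        well_h=well_h,
        um_per_px=um_per_px,
        basis=basis,
        counts=counts,
        areas_px2=areas,
        trap_positive_area_px2=trap_area,
    )


def quantify_detections(
    detections: Sequence[Detection],
    well_id: str,
    well_w: int,
    well_h: int,
    um_per_px: float,
) -> QuantificationReport:
    """Quantify model output for one well (box-union area basis)."""
    return quantify_items(detections, well_id, well_w, well_h, um_per_px, "boxes")


def quantify_annotation(
    well: WellAnnotation, um_per_px: float
) -> QuantificationReport:
    """Quantify a human/ground-truth annotation (polygon-union area basis)."""
    cells = well.all_cells()
    return quantify_items(
        cells, well.well_id, well.width, well.height, um_per_px, "polygons"
    )
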