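"""Agreement statistics between annotators and between model and annotators.

Counting and area estimation are regression tasks, so agreement between
two sources (human annotators, or the model and an annotator) is measured
as the Pearson correlation of their per-region measurement vectors over a
common set of culture regions, alongside a D'Agostino-Pearson omnibus
check that the residuals of the pairwise linear fits are normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CellType, WellAnnotation, region_grid
from .detector import Detection
from .quantify import covered_area


class AgreementError(ValueError):
    pass


def _region_of_point(
    x: float, y: float, rects: Sequence[tuple[int, int, int, int]]
) -> int:
    for i, (rx, ry, rw, rh) in enumerate(rects):
        if rx <= x < rx + rw and ry <= y < ry + rh:
            return i
    # points on the extreme right/bottom edge belong to the last region
    return len(rects) - 1


def per_region_vector(
    source: "WellAnnotation | Sequence[Detection]",
    measure: str,
    cell_type: CellType,
    grid_rows: int = 4,
    grid_cols: int = 4,
    well_w: int | None = None,
    well_h: int | None = None,
) -> np.ndarray:
    """One value per region: count or covered area of one class.

    For annotations the region partition of the well is used directly; for
    detections each box is assigned to the region containing its center, so
    a cell is never double counted across regions.  Area is the in-region
    union area (polygons for annotations, boxes for detections, clipped to
    the region).
    """
    if measure not in ("count", "area"):
        raise ValueError(f"measure must be 'count' or 'area', got {measure!r}")

    if isinstance(source, WellAnnotation):
        rects = region_grid(source.width, source.height, grid_rows, grid_cols)
        values = np.zeros(len(rects))
        cells_by_region: dict[int, list] = {i: [] for i in range(len(rects))}
        for cell, _rid in source.iter_cells_well_coords():
            if cell.cell_type is not cell_type:
                continue
            x0, y0, x1, y1 = cell.polygon.bounds
            ridx = _region_of_point((x0 + x1) / 2, (y0 + y1) / 2, rects)
            cells_by_region[ridx].append(cell)
        for i, (rx, ry, rw, rh) in enumerate(rects):
            if measure == "count":
                values[i] = len(cells_by_region[i])
            else:
                shifted = [
                    (c.polygon.shift(-rx, -ry), c.cell_type)
                    for c in cells_by_region[i]
                ]
                values[i] = covered_area(shifted, rw, rh, {cell_type})
        return values

    if well_w is None or well_h is None:
        raise ValueError("well_w and well_h are required for detection sources")
    rects = region_grid(well_w, well_h, grid_rows, grid_cols)
    values = np.zeros(len(rects))
    dets_by_region: dict[int, list] = {i: [] for i in range(len(rects))}
    for det in source:
        if det.cell_type is not cell_type:
            continue
        cx, cy = det.bbox.center
        dets_by_region[_region_of_point(cx, cy, rects)].append(det)
    for i, (rx, ry, rw, rh) in enumerate(rects):
        if measure == "count":
            values[i] = len(dets_by_region[i])
        else:
            shifted = [
                (d.bbox.shift(-rx, -ry), d.cell_type) for d in dets_by_region[i]
            ]
            values[i] = covered_area(shifted, rw, rh, {cell_type})
    return values


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on degenerate input rather than
    returning a silent 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise AgreementError("need two equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AgreementError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def drop_jointly_empty_regions(
    vectors: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Remove regions where *all* sources report zero.

    Mirrors the annotation protocol of discarding regions without any
    cells: a region is dropped only when every source agrees it is empty,
    so disagreements about near-empty regions still count.
    """
    mat = np.stack(list(vectors.values()))
    keep = mat.any(axis=0)
    return {name: v[keep] for name, v in vectors.items()}


def agreement_matrix(
    vectors: Mapping[str, np.ndarray], drop_empty: bool = True
) -> pd.DataFrame:
    """Pairwise Pearson correlations between named measurement sources.

    Returns a symmetric DataFrame with unit diagonal, indexed by source
    name in input order (read the upper triangle for the tabular layout).
    """
    if len(vectors) < 2:
        raise AgreementError("need at least two sources")
    if drop_empty:
        vectors = drop_jointly_empty_regions(vectors)
    names = list(vectors)
    n = len(names)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson_r(vectors[names[i]], vectors[names[j]])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    passed: bool


def residual_normality(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> NormalityResult:
    """D'Agostino-Pearson K² omnibus normality test on the residuals of the
    least-squares fit of y on x; passes iff p > alpha.

    Degenerate (all-zero) residuals from perfectly linear data pass by
    definition: there is no evidence of non-normality in an exact fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 8:
        raise AgreementError("normality test needs >= 8 paired observations")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    if np.allclose(resid, 0.0):
        return NormalityResult(statistic=0.0, p_value=1.0, passed=True)
    stat, p = stats.normaltest(resid)
    return NormalityResult(statistic=float(stat), p_value=float(p),
                           passed=bool(p > alpha))


def scatter_agreement(vectors: Mapping[str, np.ndarray], out_path: str) -> None:
    """Pairwise scatter plots of the per-region vectors (visual QC)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(vectors)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 4),
                             squeeze=False)
    for ax, (a, b) in zip(axes[0], pairs):
        ax.scatter(vectors[a], vectors[b], s=18, alpha=0.8)
        try:
            r = pearson_r(vectors[a], vectors[b])
            ax.set_title(f"{a} vs {b}: r={r:.3f}")
        except AgreementError:
            ax.set_title(f"{a} vs {b}")
        ax.set_xlabel(a)
        ax.set_ylabel(b)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
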