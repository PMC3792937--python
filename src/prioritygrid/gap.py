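"""Reserve gap analysis.

Reserve polygons become protected cells via an area-matching coverage
threshold: among the observed coverage fractions, pick the threshold whose
selected-cell area best matches the true total reserve area; a cell is
protected iff its coverage is strictly greater than the threshold.

Targets scale with range size: the smallest-ranged species gets 100% of its
cells, the most widespread 5%, and intermediate species are interpolated
linearly in log range size. Species are then classed as target met,
partial gap, or total gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box, shape
from shapely.ops import unary_union

from .grids import GridSpec, Layer

__all__ = [
    "reserve_coverage",
    "coverage_threshold",
    "protected_cells",
    "set_targets",
    "target_percentages",
    "gap_analysis",
    "read_reserves_geojson",
]


def read_reserves_geojson(path: str | Path, point_buffer_area: float | None = None):
    """Load reserve geometries from a GeoJSON FeatureCollection.

    Point features are mapped as circles of area ``point_buffer_area``
    (error if points are present and no area is given)."""
    with open(path) as fh:
        data = json.load(fh)
    geoms = []
    for feat in data.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "Point":
            if point_buffer_area is None:
                raise ValueError(
                    "point reserve found but no point_buffer_area given"
                )
            geom = geom.buffer(np.sqrt(point_buffer_area / np.pi), quad_segs=64)
        geoms.append(geom)
    return geoms


def reserve_coverage(spec: GridSpec, reserves: Sequence) -> Layer:
    """Fraction of each cell's area covered by the reserve union, by exact
    polygon / cell-box intersection."""
    vals = np.zeros(spec.shape)
    if reserves:
        union = unary_union(list(reserves))
        if not union.is_empty:
            minx, miny, maxx, maxy = union.bounds
            for r in range(spec.n_rows):
                for c in range(spec.n_cols):
                    x0, y0, x1, y1 = spec.cell_box(r, c)
                    if x1 <= minx or x0 >= maxx or y1 <= miny or y0 >= maxy:
                        continue
                    cell = box(x0, y0, x1, y1)
                    vals[r, c] = cell.intersection(union).area / spec.cell_area
    return Layer(spec, np.clip(vals, 0, 1), name="reserve_coverage")


def coverage_threshold(
    coverage: np.ndarray | Layer,
    cell_area: float,
    total_reserve_area: float,
) -> float:
    """Area-matching threshold over the observed coverage fractions.

    Candidates are the sorted unique coverage values; the winner minimizes
    |n_selected * cell_area - total_reserve_area| where a cell is selected
    iff coverage > threshold (strict). Ties go to the larger threshold.
    """
    vals = coverage.values if isinstance(coverage, Layer) else np.asarray(coverage)
    vals = vals[np.isfinite(vals)].ravel()
    if vals.size == 0:
        raise ValueError("no coverage values")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("coverage fractions must be in [0, 1]")
    if total_reserve_area < 0:
        raise ValueError("total_reserve_area must be >= 0")
    best_theta, best_err = None, np.inf
    for theta in np.unique(vals):
        n_sel = int(np.sum(vals > theta))
        err = abs(n_sel * cell_area - total_reserve_area)
        if err < best_err or (err == best_err):  # scan ascending: last tie wins
            best_theta, best_err = float(theta), err
    return best_theta


def protected_cells(coverage: Layer, theta: float) -> set[tuple[int, int]]:
    rows, cols = np.nonzero(coverage.values > theta)
    return {(int(r), int(c)) for r, c in zip(rows, cols)}


def target_percentages(
    range_sizes: Mapping[str, int],
    pct_smallest: float = 100.0,
    pct_largest: float = 5.0,
) -> dict[str, float]:
    """Target percentage per species, linear in log range size through
    (log r_min, pct_smallest) and (log r_max, pct_largest)."""
    if not range_sizes:
        raise ValueError("empty range-size table")
    if any(r < 1 for r in range_sizes.values()):
        raise ValueError("range sizes must be >= 1 cell")
    sizes = np.array(list(range_sizes.values()), dtype=float)
    log_min, log_max = np.log(sizes.min()), np.log(sizes.max())
    out = {}
    for sp, r in range_sizes.items():
        if log_max == log_min:
            pct = pct_smallest
        else:
            frac = (np.log(r) - log_min) / (log_max - log_min)
            pct = pct_smallest + frac * (pct_largest - pct_smallest)
        out[sp] = float(pct)
    return out


def set_targets(
    range_sizes: Mapping[str, int],
    pct_smallest: float = 100.0,
    pct_largest: float = 5.0,
) -> dict[str, int]:
    """Integer cell targets: round(pct * range / 100) to the nearest integer
    (half away from zero), clamped to [1, range]."""
    pcts = target_percentages(range_sizes, pct_smallest, pct_largest)
    targets = {}
    for sp, r in range_sizes.items():
        t = int(np.floor(pcts[sp] / 100.0 * r + 0.5))
        targets[sp] = int(np.clip(t, 1, r))
    return targets


def gap_analysis(
    ranges: Mapping[str, set],
    protected: set,
    targets: Mapping[str, int],
) -> pd.DataFrame:
    """Per-species protection report.

    Columns: range_cells, protected_cells, pct_range_protected, target_cells,
    pct_target_met (capped at 100 with the cap flagged), gap_class in
    {met, partial gap, total gap}.
    """
    protected = set(protected)
    rows = []
    for sp, cells in ranges.items():
        cells = set(cells)
        if not cells:
            raise ValueError(f"species {sp!r} has an empty range")
        t = int(targets[sp])
        p = len(cells & protected)
        pct_prot = 100.0 * p / len(cells)
        raw_met = 100.0 * p / t
        capped = raw_met > 100.0
        if p == 0:
            gap_class = "total gap"
        elif p >= t:
            gap_class = "met"
        else:
            gap_class = "partial gap"
        rows.append({
            "species": sp,
            "range_cells": len(cells),
            "protected_cells": p,
            "pct_range_protected": pct_prot,
            "target_cells": t,
            "pct_target_met": min(raw_met, 100.0),
            "target_capped": capped,
            "gap_class": gap_class,
        })
    return pd.DataFrame(rows).set_index("species")


def write_gap_report(report: pd.DataFrame, path: str | Path) -> None:
    """CSV with capped percentages encoded as an empty cell plus flag."""
    out = report.copy()
    out["pct_target_met"] = [
        "" if capped else f"{v:.2f}"
        for v, capped in zip(report["pct_target_met"], report["target_capped"])
    ]
    out.to_csv(path)
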