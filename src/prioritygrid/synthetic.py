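"""Synthetic two-resolution worlds with known ground truth.

Generates spatially autocorrelated environmental predictors, species whose
true suitability is a logistic function of a random linear combination of
predictors, presence-only records sampled inside the true range, and
rectangular reserves of known total area — everything a downstream
prioritization run needs, on a pair of nested grids.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grids import GridSpec, Layer, write_ascii_grid

__all__ = ["SyntheticWorld", "make_world", "true_metrics", "write_world"]


@dataclass
class SyntheticWorld:
    """A generated landscape with ground truth for every downstream stage."""

    fine_spec: GridSpec
    coarse_spec: GridSpec
    nesting_factor: int
    predictors: list[Layer]                 # continuous + one categorical
    true_suitability: dict[str, Layer]      # per species, in [0, 1]
    true_range: dict[str, Layer]            # per species, binary
    records: dict[str, list[tuple[float, float]]]  # per species (lon, lat)
    reserves: list                          # shapely Polygons
    reserve_fraction: float

    @property
    def species(self) -> list[str]:
        return list(self.true_range)

    @property
    def total_reserve_area(self) -> float:
        return float(sum(p.area for p in self.reserves))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Gaussian-blurred white noise, standardized to zero mean / unit sd."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                          mode="reflect")
    sd = raw.std()
    if sd == 0:
        return np.zeros(shape)
    return (raw - raw.mean()) / sd


def make_world(
    seed: int,
    fine_spec: GridSpec,
    nesting_factor: int = 4,
    n_species: int = 5,
    n_predictors: int = 4,
    records_per_species: list[int] | int = 25,
    reserve_fraction: float = 0.1,
    smooth_sigma: float = 6.0,
    signal_strength: float = 6.0,
    n_landcover_classes: int = 4,
    range_quantile: tuple[float, float] = (0.65, 0.9),
) -> SyntheticWorld:
    """Build a deterministic synthetic world from a seed.

    Parameters mirror the knobs a field dataset would fix: grid geometry,
    number of species and predictors, records per species, and the fraction
    of the study area covered by reserves (rectangles summing to within one
    fine cell's area of ``reserve_fraction`` x total area).
    """
    if n_species < 1:
        raise ValueError(f"n_species must be >= 1, got {n_species}")
    if nesting_factor < 2:
        raise ValueError(f"nesting_factor must be >= 2, got {nesting_factor}")
    if not 0 <= reserve_fraction <= 0.5:
        raise ValueError(f"reserve_fraction must be in [0, 0.5], got {reserve_fraction}")
    if isinstance(records_per_species, int):
        records_per_species = [records_per_species] * n_species
    if len(records_per_species) != n_species:
        raise ValueError("records_per_species length must equal n_species")
    if any(n < 1 for n in records_per_species):
        raise ValueError("records_per_species entries must be >= 1")

    coarse_spec = fine_spec.coarsen(nesting_factor)
    rng = np.random.default_rng(seed)
    shape = fine_spec.shape

    # predictors: smoothed continuous fields + one categorical layer
    predictors: list[Layer] = []
    for j in range(n_predictors):
        predictors.append(
            Layer(fine_spec, _smooth_field(rng, shape, smooth_sigma),
                  name=f"env{j:02d}")
        )
    landcover_field = _smooth_field(rng, shape, smooth_sigma)
    edges = np.quantile(landcover_field,
                        np.linspace(0, 1, n_landcover_classes + 1)[1:-1])
    landcover = np.digitize(landcover_field, edges).astype(float)
    predictors.append(Layer(fine_spec, landcover, name="landcover",
                            categorical=True))

    cont = np.stack([p.values for p in predictors if not p.categorical])

    true_suitability: dict[str, Layer] = {}
    true_range: dict[str, Layer] = {}
    records: dict[str, list[tuple[float, float]]] = {}
    s = fine_spec.cell_size
    for i in range(n_species):
        sp = f"sp{i:02d}"
        coef = rng.standard_normal(n_predictors)
        coef *= signal_strength / np.linalg.norm(coef)
        lin = np.tensordot(coef, cont, axes=1)
        lin -= np.median(lin)
        suit = 1.0 / (1.0 + np.exp(-lin))
        q = rng.uniform(*range_quantile)
        rng_mask = (suit >= np.quantile(suit, q)).astype(float)
        true_suitability[sp] = Layer(fine_spec, suit, name=f"{sp}_suitability")
        true_range[sp] = Layer(fine_spec, rng_mask, name=f"{sp}_range")

        rows, cols = np.nonzero(rng_mask)
        n_rec = records_per_species[i]
        if n_rec > rows.size:
            raise ValueError(
                f"species {sp}: requested {n_rec} records but true range has "
                f"only {rows.size} cells"
            )
        pick = rng.choice(rows.size, size=n_rec, replace=False)
        jitter = rng.uniform(0, 1, size=(n_rec, 2))
        pts = []
        for (r, c), (jx, jy) in zip(zip(rows[pick], cols[pick]), jitter):
            lon = fine_spec.origin_lon + (c + jx) * s
            lat = fine_spec.origin_lat - (r + jy) * s
            pts.append((float(lon), float(lat)))
        records[sp] = pts

    reserves = _make_reserves(rng, fine_spec, reserve_fraction)

    return SyntheticWorld(
        fine_spec=fine_spec,
        coarse_spec=coarse_spec,
        nesting_factor=nesting_factor,
        predictors=predictors,
        true_suitability=true_suitability,
        true_range=true_range,
        records=records,
        reserves=reserves,
        reserve_fraction=reserve_fraction,
    )


def _make_reserves(rng: np.random.Generator, spec: GridSpec,
                   fraction: float, max_attempts: int = 2000) -> list:
    """Non-overlapping cell-aligned rectangles totalling ~fraction of area.

    Stops when the remaining shortfall is under one fine cell's area, so the
    summed area is exact to within that tolerance.
    """
    if fraction <= 0:
        return []
    cell_area = spec.cell_area
    target_cells = fraction * spec.n_cells
    s = spec.cell_size
    max_side = max(2, int(round(np.sqrt(target_cells / 3))))
    reserves: list = []
    placed = np.zeros(spec.shape, dtype=bool)
    remaining = target_cells
    attempts = 0
    while remaining >= 1.0 and attempts < max_attempts:
        attempts += 1
        h = int(rng.integers(1, max_side + 1))
        w = int(rng.integers(1, max_side + 1))
        while h * w > remaining + 1:  # shrink to fit the shortfall
            if h >= w and h > 1:
                h -= 1
            elif w > 1:
                w -= 1
            else:
                break
        if h * w > remaining + 1:
            continue
        r0 = int(rng.integers(0, spec.n_rows - h + 1))
        c0 = int(rng.integers(0, spec.n_cols - w + 1))
        if placed[r0:r0 + h, c0:c0 + w].any():
            continue
        placed[r0:r0 + h, c0:c0 + w] = True
        x0 = spec.origin_lon + c0 * s
        y1 = spec.origin_lat - r0 * s
        reserves.append(box(x0, y1 - h * s, x0 + w * s, y1))
        remaining -= h * w
    return reserves


def true_metrics(world: SyntheticWorld) -> dict[str, dict[str, float]]:
    """Per-species ground truth: true range size (fine cells) and the true
    fraction of the range area inside reserves, from geometry alone."""
    out: dict[str, dict[str, float]] = {}
    union = unary_union(world.reserves) if world.reserves else None
    spec = world.fine_spec
    for sp, layer in world.true_range.items():
        rows, cols = np.nonzero(layer.values)
        n_cells = rows.size
        protected_area = 0.0
        if union is not None and not union.is_empty:
            for r, c in zip(rows, cols):
                cell = box(*spec.cell_box(int(r), int(c)))
                if cell.intersects(union):
                    protected_area += cell.intersection(union).area
        total_area = n_cells * spec.cell_area
        out[sp] = {
            "range_cells": float(n_cells),
            "protected_fraction": protected_area / total_area if total_area else 0.0,
        }
    return out


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write predictors (.asc), records (CSV), and reserves (GeoJSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    pred_dir = out_dir / "predictors"
    pred_dir.mkdir(exist_ok=True)
    for layer in world.predictors:
        path = pred_dir / f"{layer.name}.asc"
        write_ascii_grid(layer, path)
        written[f"predictor:{layer.name}"] = path

    rec_path = out_dir / "records.csv"
    with open(rec_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "lon", "lat"])
        for sp, pts in world.records.items():
            for lon, lat in pts:
                writer.writerow([sp, repr(lon), repr(lat)])
    written["records"] = rec_path

    res_path = out_dir / "reserves.geojson"
    features = [
        {"type": "Feature", "properties": {"id": i}, "geometry": mapping(poly)}
        for i, poly in enumerate(world.reserves)
    ]
    with open(res_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    written["reserves"] = res_path
    return written
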