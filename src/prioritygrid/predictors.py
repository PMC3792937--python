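"""Predictor preparation: block aggregation to a coarse grid and iterative
variance-inflation-factor screening of collinear continuous layers."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, Layer

__all__ = ["PredictorStack", "aggregate", "vif_screen", "compute_vifs"]


@dataclass
class PredictorStack:
    """Named layers sharing one grid; at most one categorical layer."""

    grid: GridSpec
    layers: list[Layer]
    vifs: dict[str, float] = field(default_factory=dict)
    drop_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for layer in self.layers:
            if layer.spec != self.grid:
                raise ValueError(f"layer {layer.name!r} is not on the stack grid")
        n_cat = sum(1 for l in self.layers if l.categorical)
        if n_cat > 1:
            raise ValueError(f"at most one categorical layer allowed, got {n_cat}")

    @property
    def continuous(self) -> list[Layer]:
        return [l for l in self.layers if not l.categorical]

    @property
    def categorical(self) -> Layer | None:
        for layer in self.layers:
            if layer.categorical:
                return layer
        return None

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def matrix(self, cells: list[tuple[int, int]] | None = None,
               one_hot_categorical: bool = True) -> np.ndarray:
        """Design matrix over the given cells (default: all cells, row-major).

        The categorical layer, if any, is one-hot encoded over its observed
        classes so any learner can consume the matrix.
        """
        if cells is None:
            idx = (slice(None), slice(None))
            flat = lambda v: v[idx].ravel()
        else:
            rows = np.array([r for r, _ in cells])
            cols = np.array([c for _, c in cells])
            flat = lambda v: v[rows, cols]
        blocks = [flat(l.values) for l in self.continuous]
        cat = self.categorical
        if cat is not None:
            vals = flat(cat.values)
            if one_hot_categorical:
                classes = np.unique(cat.values[np.isfinite(cat.values)])
                for cls in classes:
                    blocks.append((vals == cls).astype(float))
            else:
                blocks.append(vals)
        return np.column_stack(blocks)


def aggregate(fine_layer: Layer, coarse_spec: GridSpec) -> Layer:
    """Aggregate a fine layer to a nested coarse grid.

    Continuous layers take the mean of each coarse cell's k*k children
    (missing children excluded); categorical layers take the modal class,
    ties broken by the smallest class code.
    """
    k = fine_layer.spec.nesting_factor(coarse_spec)
    vals = fine_layer.values
    nr, nc = coarse_spec.shape
    blocks = vals.reshape(nr, k, nc, k).transpose(0, 2, 1, 3).reshape(nr, nc, k * k)

    if fine_layer.categorical:
        out = np.full((nr, nc), np.nan)
        for r in range(nr):
            for c in range(nc):
                child = blocks[r, c]
                child = child[np.isfinite(child)]
                if child.size == 0:
                    continue
                classes, counts = np.unique(child, return_counts=True)
                out[r, c] = classes[np.argmax(counts)]  # first max = smallest code
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
            out = np.nanmean(blocks, axis=2)
    return Layer(coarse_spec, out, name=fine_layer.name,
                 categorical=fine_layer.categorical)


def aggregate_stack(stack: PredictorStack, coarse_spec: GridSpec) -> PredictorStack:
    return PredictorStack(coarse_spec,
                          [aggregate(l, coarse_spec) for l in stack.layers])


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R-squared of y on X (with intercept) by least squares."""
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def compute_vifs(layers: list[Layer]) -> dict[str, float]:
    """VIF_j = 1/(1-R2_j) from regressing each layer on all the others,
    over cells where every layer is non-missing."""
    if len(layers) < 2:
        return {l.name: 1.0 for l in layers}
    data = np.stack([l.values.ravel() for l in layers], axis=1)
    valid = np.all(np.isfinite(data), axis=1)
    data = data[valid]
    vifs: dict[str, float] = {}
    for j, layer in enumerate(layers):
        others = np.delete(data, j, axis=1)
        r2 = _ols_r2(data[:, j], others)
        vifs[layer.name] = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_screen(stack: PredictorStack, threshold: float = 5.0) -> PredictorStack:
    """Iteratively drop the largest-VIF continuous layer until all VIFs fall
    below ``threshold``.

    One layer is removed per iteration (largest VIF first; exact ties broken
    by layer name). The categorical layer is exempt and always retained. The
    returned stack records final VIFs and an ordered drop log.
    """
    continuous = list(stack.continuous)
    if len(continuous) < 2:
        warnings.warn("fewer than 2 continuous layers; VIF screening skipped")
        out = PredictorStack(stack.grid, list(stack.layers))
        out.vifs = {l.name: 1.0 for l in continuous}
        return out

    drop_log: list[dict] = []
    iteration = 0
    while len(continuous) >= 2:
        vifs = compute_vifs(continuous)
        max_vif = max(vifs.values())
        if max_vif < threshold:
            break
        # largest VIF first; exact ties resolved by layer-name order
        drop_name = sorted(name for name, v in vifs.items() if v == max_vif)[0]
        iteration += 1
        drop_log.append({"layer": drop_name, "vif_at_drop": vifs[drop_name],
                         "iteration": iteration})
        continuous = [l for l in continuous if l.name != drop_name]

    final_vifs = compute_vifs(continuous)
    kept = [l for l in stack.layers
            if l.categorical or l.name in final_vifs]
    out = PredictorStack(stack.grid, kept)
    out.vifs = final_vifs
    out.drop_log = drop_log
    return out
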