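"""Cross-resolution congruence statistics.

Pearson correlations tested against a Monte-Carlo permutation null
(one-sided, upper tail, +1 correction), arcsine transformation of
percentages, best-fraction priority envelopes, and the nestedness of fine
envelopes within coarse ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridSpec, Layer

__all__ = [
    "permutation_correlation",
    "arcsine_pct",
    "priority_envelope",
    "nestedness",
    "cross_scale_cell_pairs",
]


@dataclass
class PermutationTestResult:
    r_obs: float
    p_value: float
    n_perm: int

    @property
    def significant(self) -> bool:
        """The paper-style decision rule: non-random at p <= 0.05."""
        return self.p_value <= 0.05


def permutation_correlation(
    x, y, n_perm: int = 30000, seed: int = 0
) -> PermutationTestResult:
    """Pearson r with a permutation-null p-value.

    The null is built by permuting y (x fixed) n_perm times;
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm), one-sided upper tail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r_obs = float(np.dot(xc, yc) / (sx * sy))

    rng = np.random.default_rng(seed)
    n = x.size
    exceed = 0
    batch = max(1, min(n_perm, 10_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        done += b
        # b independent permutations of y via random-key argsort
        order = np.argsort(rng.random((b, n)), axis=1)
        r_perm = (yc[order] @ xc) / (sx * sy)
        exceed += int(np.sum(r_perm >= r_obs))
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(r_obs=r_obs, p_value=float(p), n_perm=n_perm)


def arcsine_pct(p) -> np.ndarray | float:
    """arcsin(sqrt(p/100)) in radians for percentages in [0, 100]; values
    above 100 are capped to 100 before transforming."""
    arr = np.asarray(p, dtype=float)
    capped = np.minimum(arr, 100.0)
    if np.any(capped < 0) or np.any(~np.isfinite(capped)):
        raise ValueError("percentages must be finite and >= 0")
    out = np.arcsin(np.sqrt(capped / 100.0))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def priority_envelope(
    layer: Layer, fraction: float = 0.01
) -> tuple[set[tuple[int, int]], float]:
    """Top-priority envelope: cells with score strictly above the threshold
    whose selected count is closest to fraction * N (ties -> fewer cells).

    Returns (cell set, realized fraction). A constant layer has no
    meaningful envelope and raises."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    vals = layer.values
    finite = np.isfinite(vals)
    scores = vals[finite]
    if scores.size == 0:
        raise ValueError("layer has no scored cells")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("constant layer: no meaningful envelope")
    n_total = scores.size
    want = fraction * n_total
    best_theta, best_err, best_count = None, np.inf, None
    for theta in uniq:  # ascending: later thresholds select fewer cells
        count = int(np.sum(scores > theta))
        err = abs(count - want)
        if err < best_err or (err == best_err and count < best_count):
            best_theta, best_err, best_count = float(theta), err, count
    rows, cols = np.nonzero(finite & (vals > best_theta))
    cells = {(int(r), int(c)) for r, c in zip(rows, cols)}
    return cells, len(cells) / n_total


def nestedness(
    fine_envelope: set[tuple[int, int]],
    coarse_envelope: set[tuple[int, int]],
    nesting_factor: int,
) -> float:
    """Percentage of fine-envelope cells whose parent coarse cell is in the
    coarse envelope."""
    if not fine_envelope:
        raise ValueError("fine envelope is empty")
    k = nesting_factor
    inside = sum(1 for (r, c) in fine_envelope
                 if (r // k, c // k) in coarse_envelope)
    return 100.0 * inside / len(fine_envelope)


def cross_scale_cell_pairs(
    coarse_layer: Layer,
    fine_layer: Layer,
    mode: str = "replicate",
) -> tuple[np.ndarray, np.ndarray]:
    """Pair fine-grid values with coarse-grid values on nested grids.

    ``replicate`` (default): one pair per fine cell — its value against its
    parent's value. ``aggregate``: one pair per coarse cell — the mean of
    its fine children against its own value. NaN pairs are dropped.
    """
    k = fine_layer.spec.nesting_factor(coarse_layer.spec)
    fine = fine_layer.values
    coarse = coarse_layer.values
    nr, nc = coarse_layer.spec.shape
    if mode == "replicate":
        parent = np.repeat(np.repeat(coarse, k, axis=0), k, axis=1)
        ok = np.isfinite(fine) & np.isfinite(parent)
        return coarse_vals_fine_vals(parent[ok], fine[ok])
    if mode == "aggregate":
        blocks = fine.reshape(nr, k, nc, k).transpose(0, 2, 1, 3).reshape(nr, nc, k * k)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            agg = np.nanmean(blocks, axis=2)
        ok = np.isfinite(agg) & np.isfinite(coarse)
        return coarse_vals_fine_vals(coarse[ok], agg[ok])
    raise ValueError(f"unknown mode {mode!r}; use 'replicate' or 'aggregate'")


def coarse_vals_fine_vals(coarse_vals: np.ndarray,
                          fine_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(coarse_vals, dtype=float), np.asarray(fine_vals, dtype=float)
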