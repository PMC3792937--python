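"""Per-cell conservation priority indices.

Three indices share one grid: species richness (presence counts),
conservation value (irreplaceability with no cell protected), and
complementarity (irreplaceability of unprotected cells crediting existing
reserves toward the targets).

Irreplaceability of a cell is the definitional ratio: among cell
combinations that meet every species' target, the fraction that both
contain the focal cell and would fail if it were removed. Combinations
range over all subset sizes. An exact enumerator handles small instances; a
Bernoulli(1/2) subset sampler — uniform over all subsets — estimates the
same ratio at scale, with a binomial standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from .grids import GridSpec, Layer

__all__ = [
    "TargetSet",
    "richness",
    "irreplaceability_exact",
    "irreplaceability_sampled",
    "irreplaceability_importance",
    "conservation_value",
    "complementarity",
    "PriorityMaps",
]

EXACT_LIMIT = 20

Cell = Hashable


@dataclass
class TargetSet:
    """Per-species range cell-sets and integer targets, plus an optional
    protected cell-set whose overlap counts toward each target."""

    ranges: dict[str, frozenset]
    targets: dict[str, int]
    protected: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.ranges = {s: frozenset(c) for s, c in self.ranges.items()}
        self.protected = frozenset(self.protected)
        for s, t in self.targets.items():
            if s not in self.ranges:
                raise ValueError(f"target for unknown species {s!r}")
            if t < 1:
                raise ValueError(f"target for {s!r} must be >= 1, got {t}")
            if t > len(self.ranges[s]):
                raise ValueError(
                    f"target for {s!r} ({t}) exceeds its range size "
                    f"({len(self.ranges[s])})"
                )

    def locked(self, species: str) -> int:
        return len(self.protected & self.ranges[species])


def richness(ranges: Mapping[str, Layer] | Sequence[Layer]) -> Layer:
    """Count of species present per cell."""
    layers = list(ranges.values()) if isinstance(ranges, Mapping) else list(ranges)
    if not layers:
        raise ValueError("richness requires a grid: pass at least one layer")
    spec = layers[0].spec
    total = np.zeros(spec.shape)
    for layer in layers:
        if layer.spec != spec:
            raise ValueError(f"layer {layer.name!r} is on a different grid")
        total += np.nan_to_num(layer.values)
    return Layer(spec, total, name="richness")


def _masks_and_needs(cells: Sequence[Cell], targets: TargetSet,
                     ) -> tuple[list[int], list[int], list[str]]:
    """Per-species bitmask over the cell list and residual need after the
    locked (protected) contribution. Species already satisfied are dropped."""
    index = {cell: i for i, cell in enumerate(cells)}
    if len(index) != len(cells):
        raise ValueError("duplicate cells in the available set")
    masks, needs, names = [], [], []
    for sp, rng in targets.ranges.items():
        t = targets.targets.get(sp)
        if t is None:
            continue
        need = t - targets.locked(sp)
        if need <= 0:
            continue
        mask = 0
        for cell in rng:
            i = index.get(cell)
            if i is not None:
                mask |= 1 << i
        masks.append(mask)
        needs.append(need)
        names.append(sp)
    return masks, needs, names


def _check_feasible(masks: list[int], needs: list[int], names: list[str]) -> None:
    bad = [name for mask, need, name in zip(masks, needs, names)
           if mask.bit_count() < need]
    if bad:
        raise ValueError(
            "targets infeasible even selecting every available cell for "
            f"species: {', '.join(sorted(bad))}"
        )


def irreplaceability_exact(
    cells: Sequence[Cell],
    targets: TargetSet,
    exact_limit: int = EXACT_LIMIT,
) -> dict[Cell, float]:
    """Exact irreplaceability by full subset enumeration (2^n subsets).

    A subset C meets the targets iff for every species s,
    |C ∩ R_s| + |P ∩ R_s| >= t_s. Irr(x) = #{C containing x that meet but
    fail without x} / #{C that meet}.
    """
    cells = list(cells)
    n = len(cells)
    if n > exact_limit:
        raise ValueError(
            f"{n} cells exceeds exact_limit={exact_limit}; use "
            "irreplaceability_sampled"
        )
    masks, needs, names = _masks_and_needs(cells, targets)
    _check_feasible(masks, needs, names)
    if not masks:  # every target already met by the locked contribution
        return {cell: 0.0 for cell in cells}

    subsets = np.arange(1 << n, dtype=np.uint64)
    meets = np.ones(1 << n, dtype=bool)
    counts = []
    for mask, need in zip(masks, needs):
        cnt = np.bitwise_count(subsets & np.uint64(mask))
        counts.append(cnt)
        meets &= cnt >= need
    n_meet = int(meets.sum())
    if n_meet == 0:
        raise ValueError("no subset meets the targets")  # unreachable: feasible

    # a member x of a meeting C is critical iff some species with x in its
    # range sits exactly at its residual need within C
    critical = np.zeros((n, 1 << n), dtype=bool)
    for mask, need, cnt in zip(masks, needs, counts):
        tight = meets & (cnt == need)
        for i in range(n):
            if mask >> i & 1:
                critical[i] |= tight & (subsets >> np.uint64(i) & np.uint64(1)).astype(bool)
    crit_counts = critical.sum(axis=1)
    return {cell: float(crit_counts[i]) / n_meet for i, cell in enumerate(cells)}


def irreplaceability_sampled(
    cells: Sequence[Cell],
    targets: TargetSet,
    n_samples: int = 10000,
    seed: int = 0,
) -> tuple[dict[Cell, float], dict[Cell, float]]:
    """Monte-Carlo estimate of the same ratio, with standard errors.

    Subsets are drawn by independent Bernoulli(1/2) inclusion per cell,
    which is uniform over all 2^n subsets, so among sampled subsets the
    meeting ones are uniform over the meeting family and the per-cell
    estimate is a simple proportion with binomial SE.
    """
    if n_samples < 1000:
        raise ValueError(f"n_samples must be >= 1000, got {n_samples}")
    cells = list(cells)
    n = len(cells)
    masks, needs, names = _masks_and_needs(cells, targets)
    _check_feasible(masks, needs, names)
    if not masks:
        zeros = {cell: 0.0 for cell in cells}
        return zeros, dict(zeros)

    rng = np.random.default_rng(seed)
    sp_members = [np.array([i for i in range(n) if mask >> i & 1])
                  for mask in masks]
    crit = np.zeros(n, dtype=np.int64)
    n_meet = 0
    batch = 4096
    done = 0
    while done < n_samples:
        b = min(batch, n_samples - done)
        done += b
        draws = rng.random((b, n)) < 0.5
        counts = np.stack([draws[:, mem].sum(axis=1) for mem in sp_members])
        meets = np.all(counts >= np.array(needs)[:, None], axis=0)
        n_meet += int(meets.sum())
        # criticality is a union over species: count each (subset, cell) once
        crit_b = np.zeros((b, n), dtype=bool)
        for mem, cnt, need in zip(sp_members, counts, needs):
            tight = meets & (cnt == need)
            if tight.any():
                sub = np.ix_(tight, mem)
                crit_b[sub] |= draws[sub]
        crit += crit_b.sum(axis=0)
    if n_meet == 0:
        raise ValueError(
            "no sampled subset met the targets; increase n_samples or check "
            "feasibility"
        )
    est, se = {}, {}
    for i, cell in enumerate(cells):
        p = crit[i] / n_meet
        est[cell] = float(p)
        se[cell] = float(np.sqrt(max(p * (1 - p), 0.0) / n_meet))
    return est, se


def _reduce_forced(masks: list[int], needs: list[int], names: list[str]
                   ) -> tuple[int, list[int], list[int], list[str]]:
    """Exact reduction: a species whose residual need equals its available
    cell count forces all those cells into every meeting subset (their
    irreplaceability is exactly 1). Forced cells are locked in, other
    species' needs are decremented by their overlap, and the rule is
    re-applied until stable. Returns (forced bitmask, residual problem)."""
    masks, needs, names = list(masks), list(needs), list(names)
    forced = 0
    while True:
        newly = 0
        for mask, need in zip(masks, needs):
            if need >= 1 and mask.bit_count() == need:
                newly |= mask
        newly &= ~forced
        if not newly:
            break
        forced |= newly
        for j in range(len(masks)):
            needs[j] -= (masks[j] & newly).bit_count()
            masks[j] &= ~newly
    keep = [j for j in range(len(masks)) if needs[j] > 0]
    return (forced, [masks[j] for j in keep], [needs[j] for j in keep],
            [names[j] for j in keep])


def irreplaceability_importance(
    cells: Sequence[Cell],
    targets: TargetSet,
    n_samples: int = 10000,
    seed: int = 0,
    max_tilt: float = 0.98,
) -> tuple[dict[Cell, float], dict[Cell, float]]:
    """Estimate the same definitional ratio at scales where uniform subset
    sampling almost never meets the targets.

    Two exact steps make the rare event tractable: the forced-cell reduction
    (see ``_reduce_forced``), then self-normalized importance sampling of
    the residual problem with per-cell inclusion probability
    q_i = clip(max_s need_s / |R_s available|, 1/2, max_tilt), reweighted to
    the uniform-over-subsets measure. Standard errors use the effective
    sample size of the weights.
    """
    cells = list(cells)
    n = len(cells)
    masks, needs, names = _masks_and_needs(cells, targets)
    _check_feasible(masks, needs, names)
    est = {cell: 0.0 for cell in cells}
    se = {cell: 0.0 for cell in cells}
    if not masks:
        return est, se

    forced, masks, needs, names = _reduce_forced(masks, needs, names)
    for i in range(n):
        if forced >> i & 1:
            est[cells[i]] = 1.0
    if not masks:
        return est, se

    free = [i for i in range(n) if not (forced >> i & 1)]
    free_pos = {i: j for j, i in enumerate(free)}
    m = len(free)
    members = []
    for mask in masks:
        members.append(np.array([free_pos[i] for i in range(n)
                                 if mask >> i & 1 and i in free_pos]))
    needs_arr = np.array(needs)

    q = np.full(m, 0.5)
    for mem, need in zip(members, needs_arr):
        np.maximum.at(q, mem, need / len(mem))
    q = np.clip(q, 0.5, max_tilt)
    logw_in = np.log(0.5 / q)
    logw_out = np.log(0.5 / (1.0 - q))

    rng = np.random.default_rng(seed)
    meet_logw: list[np.ndarray] = []
    meet_draws: list[np.ndarray] = []
    batch = max(1, min(4096, 50_000_000 // max(m, 1)))
    done = 0
    while done < n_samples:
        b = min(batch, n_samples - done)
        done += b
        draws = rng.random((b, m)) < q
        counts = np.stack([draws[:, mem].sum(axis=1) for mem in members])
        meets = np.all(counts >= needs_arr[:, None], axis=0)
        if meets.any():
            dm = draws[meets]
            meet_logw.append(dm @ logw_in + (~dm) @ logw_out)
            meet_draws.append(dm)
    if not meet_logw:
        raise ValueError(
            "no sampled subset met the targets; increase n_samples"
        )
    logw = np.concatenate(meet_logw)
    dm = np.vstack(meet_draws)
    w = np.exp(logw - logw.max())
    sw = float(w.sum())
    n_eff = sw**2 / float((w**2).sum())

    counts = np.stack([dm[:, mem].sum(axis=1) for mem in members])
    crit = np.zeros((dm.shape[0], m), dtype=bool)
    for mem, cnt, need in zip(members, counts, needs_arr):
        tight = cnt == need
        if tight.any():
            sub = np.ix_(tight, mem)
            crit[sub] |= dm[sub]
    crit_w = w @ crit
    for j, i in enumerate(free):
        p = crit_w[j] / sw
        est[cells[i]] = float(p)
        se[cells[i]] = float(np.sqrt(max(p * (1 - p), 0.0) / n_eff))
    return est, se


def _scores_to_layer(spec: GridSpec, scores: Mapping[tuple[int, int], float],
                     name: str, mask_cells: frozenset = frozenset()) -> Layer:
    vals = np.zeros(spec.shape)
    for (r, c), v in scores.items():
        vals[r, c] = v
    for r, c in mask_cells:
        vals[r, c] = np.nan
    return Layer(spec, vals, name=name)


def _irr_dispatch(cells, targets, exact_limit, n_samples, seed):
    if len(cells) <= exact_limit:
        return irreplaceability_exact(cells, targets, exact_limit)
    est, _ = irreplaceability_importance(cells, targets, n_samples, seed)
    return est


def conservation_value(
    spec: GridSpec,
    targets: TargetSet,
    exact_limit: int = EXACT_LIMIT,
    n_samples: int = 10000,
    seed: int = 0,
) -> Layer:
    """Irreplaceability over all range-bearing cells with nothing protected;
    cells outside every range score 0."""
    unlocked = TargetSet(targets.ranges, targets.targets, frozenset())
    cells = sorted(set().union(*unlocked.ranges.values())) if unlocked.ranges else []
    scores = _irr_dispatch(cells, unlocked, exact_limit, n_samples, seed)
    return _scores_to_layer(spec, scores, "conservation_value")


def complementarity(
    spec: GridSpec,
    targets: TargetSet,
    exact_limit: int = EXACT_LIMIT,
    n_samples: int = 10000,
    seed: int = 0,
) -> Layer:
    """Irreplaceability of unprotected cells, crediting protected overlap
    toward each target; protected cells are masked (NaN) in the output."""
    cells = sorted(
        (set().union(*targets.ranges.values()) if targets.ranges else set())
        - set(targets.protected)
    )
    scores = _irr_dispatch(cells, targets, exact_limit, n_samples, seed)
    return _scores_to_layer(spec, scores, "complementarity",
                            mask_cells=targets.protected)


@dataclass
class PriorityMaps:
    """The three priority indices on one grid."""

    richness: Layer
    conservation_value: Layer
    complementarity: Layer

    def __post_init__(self) -> None:
        spec = self.richness.spec
        if self.conservation_value.spec != spec or self.complementarity.spec != spec:
            raise ValueError("priority layers must share one grid")
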