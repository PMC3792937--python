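"""Presence / pseudo-absence ensemble modeling.

Per species: draw pseudo-absences, cross-validate a set of learners, build
an AUC-weighted consensus suitability surface (learners with cross-validated
AUC <= 0.7 get zero weight), pick a commission-minimizing binarization
threshold, force recorded cells to presence, and clip the binary surface to
a record-anchored range by removing patches isolated from the records by
more than the mean nearest-neighbour record distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.ndimage import label as _label
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .grids import GridSpec, Layer
from .predictors import PredictorStack

__all__ = [
    "Learner",
    "default_learners",
    "sample_pseudo_absences",
    "auc",
    "fit_ensemble",
    "select_threshold",
    "binarize_with_override",
    "barrier_clip",
    "EnsembleResult",
    "SpeciesRange",
]

AUC_CUTOFF = 0.7


@dataclass
class Learner:
    """A named binary classifier factory. ``factory(seed)`` must return an
    unfitted estimator with fit / predict_proba mapping feature vectors to
    scores in [0, 1]."""

    name: str
    factory: Callable[[int], object]


def default_learners() -> list[Learner]:
    """Linear-logistic, boosted-tree, and randomized-tree-ensemble learners."""
    return [
        Learner("logistic", lambda seed: make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=1000, random_state=seed))),
        Learner("boosted_trees", lambda seed: GradientBoostingClassifier(
            n_estimators=100, max_depth=2, random_state=seed)),
        Learner("random_forest", lambda seed: RandomForestClassifier(
            n_estimators=200, min_samples_leaf=2, random_state=seed)),
    ]


def sample_pseudo_absences(
    grid: GridSpec,
    presence_cells: set[tuple[int, int]],
    n: int,
    seed: int,
) -> set[tuple[int, int]]:
    """Draw ``n`` distinct background cells uniformly from cells without a
    presence. Deterministic per seed."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    available = [cell for cell in grid.iter_cells() if cell not in presence_cells]
    if len(available) < n:
        raise ValueError(
            f"requested {n} pseudo-absences but only {len(available)} "
            f"non-presence cells available (short by {n - len(available)})"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(available), size=n, replace=False)
    return {available[i] for i in pick}


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUC: probability a random positive outscores a random
    negative, ties counted one half (Mann-Whitney form)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    u = float(np.sum(ranks[labels == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass
class EnsembleResult:
    species: str
    learner_aucs: dict[str, float]
    weights: dict[str, float]
    consensus: Layer | None
    learner_predictions: dict[str, Layer] = field(default_factory=dict)
    usable: bool = True
    threshold: float | None = None
    threshold_criterion: str | None = None


def fit_ensemble(
    predictors: PredictorStack,
    presences: set[tuple[int, int]],
    pseudo_absences: set[tuple[int, int]],
    learners: Sequence[Learner] | None = None,
    folds: int = 10,
    seed: int = 0,
    species: str = "",
    auc_cutoff: float = AUC_CUTOFF,
) -> EnsembleResult:
    """Cross-validate each learner, then refit on all data and average the
    cell-wise predictions of learners with AUC > ``auc_cutoff``, weighting
    by raw AUC. If no learner passes, the result is flagged unusable."""
    if len(presences) < 2:
        raise ValueError(f"need >= 2 presences, got {len(presences)}")
    if learners is None:
        learners = default_learners()
    if not learners:
        raise ValueError("learner set is empty")

    cells = sorted(presences) + sorted(pseudo_absences)
    y = np.array([1] * len(presences) + [0] * len(pseudo_absences))
    X = predictors.matrix(cells)
    ok = np.all(np.isfinite(X), axis=1)
    X, y = X[ok], y[ok]
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("degenerate training set after removing missing cells")

    n_splits = min(folds, n_pos, n_neg)
    if n_splits < 2:
        raise ValueError("cannot form >= 2 stratified folds")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)

    # score all grid cells with complete predictor data
    all_cells = list(predictors.grid.iter_cells())
    X_all = predictors.matrix(all_cells)
    finite_all = np.all(np.isfinite(X_all), axis=1)

    learner_aucs: dict[str, float] = {}
    learner_predictions: dict[str, Layer] = {}
    for li, learner in enumerate(learners):
        fold_aucs = []
        for fi, (train, test) in enumerate(cv.split(X, y)):
            if len(np.unique(y[test])) < 2:  # stratification should prevent this
                continue
            est = learner.factory(seed + 1000 * li + fi)
            est.fit(X[train], y[train])
            scores = est.predict_proba(X[test])[:, 1]
            fold_aucs.append(auc(y[test], scores))
        if not fold_aucs:
            raise ValueError(f"learner {learner.name}: all folds degenerate")
        learner_aucs[learner.name] = float(np.mean(fold_aucs))

        est = learner.factory(seed + 1000 * li + 999)
        est.fit(X, y)
        pred = np.full(predictors.grid.n_cells, np.nan)
        pred[finite_all] = est.predict_proba(X_all[finite_all])[:, 1]
        learner_predictions[learner.name] = Layer(
            predictors.grid, pred.reshape(predictors.grid.shape),
            name=f"{species}_{learner.name}")

    weights = {name: (a if a > auc_cutoff else 0.0)
               for name, a in learner_aucs.items()}
    total = sum(weights.values())
    if total == 0:
        return EnsembleResult(species, learner_aucs, weights, None,
                              learner_predictions, usable=False)

    consensus = np.zeros(predictors.grid.shape)
    for name, w in weights.items():
        if w > 0:
            consensus = consensus + w * learner_predictions[name].values
    consensus = consensus / total
    hs = Layer(predictors.grid, consensus, name=f"{species}_consensus")
    return EnsembleResult(species, learner_aucs, weights, hs,
                          learner_predictions, usable=True)


def _confusion_stats(labels: np.ndarray, scores: np.ndarray,
                     theta: float) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, kappa) for rule score >= theta."""
    pred = scores >= theta
    pos = labels == 1
    tp = float(np.sum(pred & pos))
    tn = float(np.sum(~pred & ~pos))
    fp = float(np.sum(pred & ~pos))
    fn = float(np.sum(~pred & pos))
    n = tp + tn + fp + fn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / n
    p_yes = ((tp + fp) / n) * ((tp + fn) / n)
    p_no = ((tn + fn) / n) * ((tn + fp) / n)
    pe = p_yes + p_no
    kappa = 0.0 if pe == 1 else (acc - pe) / (1 - pe)
    return sens, spec, acc, kappa


def select_threshold(
    labels: Sequence[int],
    scores: Sequence[float],
    sensitivity_floor: float = 0.9,
) -> tuple[float, str]:
    """Commission-minimizing threshold: the maximum of four candidates
    computed over the sorted unique scores —

    - ``sensitivity``: largest theta keeping sensitivity >= the floor
      (minimal-predicted-area criterion),
    - ``accuracy``: argmax overall accuracy,
    - ``kappa``: argmax Cohen's kappa,
    - ``tss``: argmax sensitivity + specificity - 1,

    ties within a criterion resolved toward the larger theta. Returns
    (threshold, winning criterion label)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold selection requires both classes")
    cand = np.unique(scores)

    stats = np.array([_confusion_stats(labels, scores, t) for t in cand])
    sens, spec, acc, kappa = stats.T
    tss = sens + spec - 1

    choices: dict[str, float] = {}
    feasible = cand[sens >= sensitivity_floor]
    if feasible.size:
        choices["sensitivity"] = float(feasible.max())
    # argmax with ties toward larger theta: scan candidates in ascending
    # order and keep the last index attaining the max
    for name, vals in (("accuracy", acc), ("kappa", kappa), ("tss", tss)):
        best = np.max(vals)
        choices[name] = float(cand[np.nonzero(vals == best)[0][-1]])

    theta = max(choices.values())
    criterion = next(k for k, v in choices.items() if v == theta)
    return theta, criterion


def binarize_with_override(
    hs: Layer,
    theta: float,
    record_cells: set[tuple[int, int]],
) -> Layer:
    """Cell = 1 iff suitability >= theta, with recorded cells forced to 1
    regardless of the model prediction."""
    if not 0 <= theta <= 1:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    binary = (hs.values >= theta).astype(float)
    binary[np.isnan(hs.values)] = 0.0
    for r, c in record_cells:
        binary[r, c] = 1.0
    return Layer(hs.spec, binary, name=hs.name + "_binary")


@dataclass
class SpeciesRange:
    """A clipped binary range plus its provenance."""

    binary: Layer
    record_cells: set[tuple[int, int]]
    component_labels: np.ndarray
    mean_nn_distance: float

    @property
    def cells(self) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(self.binary.values)
        return {(int(r), int(c)) for r, c in zip(rows, cols)}

    @property
    def size(self) -> int:
        return int(np.sum(self.binary.values == 1))


def mean_nn_distance(records: Sequence[tuple[float, float]]) -> float:
    """Mean over records of the Euclidean distance to the nearest other
    record; defined as 0 for a single record."""
    if len(records) == 0:
        raise ValueError("at least one record required")
    if len(records) == 1:
        return 0.0
    pts = np.asarray(records, dtype=float)
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def barrier_clip(
    binary: Layer,
    records: Sequence[tuple[float, float]],
    chain: bool = False,
) -> SpeciesRange:
    """Remove suitable patches isolated from the records.

    Connected components (8-connectivity) of the binary layer that contain a
    record cell are always retained. A recordless component is retained iff
    its minimum cell-centre distance to a record-containing component is at
    most the mean nearest-neighbour record distance d-bar. With
    ``chain=True`` newly retained components can in turn anchor others
    (iterate to a fixpoint); default is the single pass.
    """
    if len(records) == 0:
        raise ValueError("at least one record required")
    spec = binary.spec
    record_cells = {spec.cell_of(lon, lat) for lon, lat in records}
    vals = (binary.values == 1).astype(int)
    for r, c in record_cells:
        vals[r, c] = 1  # record cells always count as present

    structure = np.ones((3, 3), dtype=int)
    labels, n_comp = _label(vals, structure=structure)
    d_bar = mean_nn_distance(records)

    anchored = {int(labels[r, c]) for r, c in record_cells}
    anchored.discard(0)

    lon_c, lat_c = spec.centers()
    comp_coords = {
        comp: np.column_stack([lon_c[labels == comp], lat_c[labels == comp]])
        for comp in range(1, n_comp + 1)
    }

    retained = set(anchored)
    frontier = set(anchored)
    while frontier:
        new: set[int] = set()
        for comp in range(1, n_comp + 1):
            if comp in retained:
                continue
            for anchor in frontier:
                if cdist(comp_coords[comp], comp_coords[anchor]).min() <= d_bar:
                    new.add(comp)
                    break
        retained |= new
        frontier = new if chain else set()

    keep = np.isin(labels, sorted(retained))
    out_vals = np.where(keep, vals, 0).astype(float)
    out_labels = np.where(keep, labels, 0)
    return SpeciesRange(
        binary=Layer(spec, out_vals, name=binary.name + "_clipped"),
        record_cells=record_cells,
        component_labels=out_labels,
        mean_nn_distance=d_bar,
    )


def single_cell_range(spec: GridSpec, record: tuple[float, float],
                      name: str = "") -> SpeciesRange:
    """Range for a species below the modeling threshold: exactly the one
    occupied cell, no model involved."""
    cell = spec.cell_of(*record)
    vals = np.zeros(spec.shape)
    vals[cell] = 1.0
    labels = np.zeros(spec.shape, dtype=int)
    labels[cell] = 1
    return SpeciesRange(
        binary=Layer(spec, vals, name=name or "single_record_range"),
        record_cells={cell},
        component_labels=labels,
        mean_nn_distance=0.0,
    )
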