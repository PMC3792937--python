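import numpy as np
import pytest
from scipy.spatial.distance import cdist

from prioritygrid.grids import GridSpec, Layer
from prioritygrid.predictors import PredictorStack
from prioritygrid.sdm import (
    Learner,
    auc,
    barrier_clip,
    binarize_with_override,
    default_learners,
    fit_ensemble,
    mean_nn_distance,
    sample_pseudo_absences,
    select_threshold,
    single_cell_range,
)


class TestPseudoAbsences:
    def test_forced_outcome(self):
        spec = GridSpec(0, 5, 1.0, 5, 5)
        free = {(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2), (2, 0),
                (2, 1), (2, 2), (3, 0)}
        presences = set(spec.iter_cells()) - free
        assert sample_pseudo_absences(spec, presences, 10, seed=1) == free

    def test_deterministic(self):
        spec = GridSpec(0, 10, 1.0, 10, 10)
        presences = {(0, 0), (5, 5)}
        a = sample_pseudo_absences(spec, presences, 30, seed=42)
        b = sample_pseudo_absences(spec, presences, 30, seed=42)
        assert a == b
        assert len(a) == 30
        assert not a & presences

    def test_insufficient_cells(self):
        spec = GridSpec(0, 2, 1.0, 2, 2)
        with pytest.raises(ValueError, match="short by"):
            sample_pseudo_absences(spec, {(0, 0)}, 4, seed=0)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties(self):
        assert auc([1, 0], [0.4, 0.4]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1, 1], [0.5, 0.6])

    def test_against_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(30), 1)  # force some ties
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc(labels, scores) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_random_scores_near_half(self):
        # Monte-Carlo: mean AUC of random scores within 0.02 of 0.5
        rng = np.random.default_rng(1)
        vals = []
        labels = np.array([1] * 1000 + [0] * 1000)
        for _ in range(500):
            vals.append(auc(labels, rng.random(2000)))
        assert abs(np.mean(vals) - 0.5) < 0.02


class TestSelectThreshold:
    def test_minimal_predicted_area_brute_force(self):
        # 10 presences scored 0.1..1.0: largest theta keeping sensitivity
        # >= 0.9 is 0.2 (keeps 9 of 10), by exhaustive cut-point scan
        pres = np.round(np.arange(0.1, 1.01, 0.1), 1)
        labels = [1] * 10 + [0] * 5
        scores = list(pres) + [0.01, 0.02, 0.03, 0.04, 0.05]
        feasible = [t for t in sorted(set(scores))
                    if np.mean(pres >= t) >= 0.9]
        assert max(feasible) == pytest.approx(0.2)
        theta, _ = select_threshold(labels, scores)
        assert theta >= 0.2  # the reported theta is the max of four criteria

    def test_max_rule(self):
        # engineered so each criterion is computable and the max is returned
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.3, 0.4, 0.2, 0.1, 0.05]
        theta, criterion = select_threshold(labels, scores, sensitivity_floor=0.5)
        cands = {}
        uniq = sorted(set(scores))
        lab = np.array(labels)
        sc = np.array(scores)
        for t in uniq:
            pred = sc >= t
            sens = np.mean(pred[lab == 1])
            spec = np.mean(~pred[lab == 0])
            if sens >= 0.5:
                cands.setdefault("sens", []).append(t)
        assert theta == pytest.approx(max(max(v) for v in cands.values()))

    def test_perfectly_separated(self):
        labels = [0, 0, 0, 1, 1, 1]
        scores = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        theta, _ = select_threshold(labels, scores)
        # with a 0.9 floor and only 3 presences, sensitivity >= 0.9 forces
        # all presences kept -> theta at most the smallest positive score;
        # every criterion lands inside or at the edge of the gap
        pred_pos = np.array([s >= theta for s in scores[3:]])
        pred_neg = np.array([s >= theta for s in scores[:3]])
        assert pred_pos.all() and not pred_neg.any()

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            select_threshold([1, 1], [0.1, 0.2])


class TestBinarize:
    def test_record_override(self):
        spec = GridSpec(0, 3, 1.0, 3, 3)
        hs = Layer(spec, np.zeros((3, 3)))
        out = binarize_with_override(hs, 0.5, {(1, 1)})
        assert out.values[1, 1] == 1
        assert out.values.sum() == 1

    def test_theta_zero_all_present(self):
        spec = GridSpec(0, 2, 1.0, 2, 2)
        hs = Layer(spec, np.array([[0.0, 0.2], [0.5, 1.0]]))
        out = binarize_with_override(hs, 0.0, set())
        assert out.values.sum() == 4

    def test_theta_one_none_present(self):
        spec = GridSpec(0, 2, 1.0, 2, 2)
        hs = Layer(spec, np.array([[0.0, 0.2], [0.5, 0.99]]))
        out = binarize_with_override(hs, 1.0, set())
        assert out.values.sum() == 0

    def test_monotone_shrinkage(self):
        spec = GridSpec(0, 5, 1.0, 5, 5)
        rng = np.random.default_rng(2)
        hs = Layer(spec, rng.random((5, 5)))
        records = {(0, 0)}
        prev = None
        for theta in [0.0, 0.25, 0.5, 0.75, 1.0]:
            cur = binarize_with_override(hs, theta, records).values
            if prev is not None:
                assert np.all(cur <= prev)  # raising theta never adds cells
            assert cur[0, 0] == 1
            prev = cur


class TestBarrierClip:
    def _grid(self):
        return GridSpec(0.0, 20.0, 1.0, 20, 20)

    def test_hand_constructed_gap_case(self):
        # patch A (with records), recordless patch B at gap 2 cells (kept,
        # <= d-bar), recordless patch C at gap 5 cells (removed)
        spec = self._grid()
        vals = np.zeros((20, 20))
        vals[9:12, 0:3] = 1        # patch A: cols 0-2
        vals[9:12, 5:8] = 1        # patch B: gap of cols 3,4 (2 cells)
        vals[9:12, 13:16] = 1      # patch C: gap of cols 8..12 (5 cells)
        # two records inside A, offset (2, 3) -> each NN distance is
        # sqrt(13) ~ 3.6, verified by exhaustive pair scan below
        records = [(0.5, 9.5), (2.5, 6.5)]
        pts = np.array(records)
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        d_bar = float(d.min(axis=1).mean())
        assert d_bar == pytest.approx(np.hypot(2.0, 3.0))
        assert 3 < d_bar < 4
        out = barrier_clip(Layer(spec, vals), records)
        assert out.mean_nn_distance == pytest.approx(d_bar)
        kept = out.binary.values
        assert kept[10, 1] == 1      # A kept (has records)
        # B: min centre distance between col-2 cells and col-5 cells = 3 <= d_bar
        assert kept[10, 6] == 1
        # C: min centre distance from B cols 5-7 is 6 > d_bar, from A is 11
        assert kept[10, 14] == 0

    def test_records_in_both_patches_kept(self):
        spec = self._grid()
        vals = np.zeros((20, 20))
        vals[0:2, 0:2] = 1
        vals[18:20, 18:20] = 1
        records = [(0.5, 19.5), (18.5, 0.5)]  # one per patch, huge gap
        out = barrier_clip(Layer(spec, vals), records)
        assert out.binary.values[0, 0] == 1
        assert out.binary.values[19, 19] == 1

    def test_single_record_d_bar_zero(self):
        assert mean_nn_distance([(1.0, 1.0)]) == 0.0

    def test_single_record_only_component(self):
        spec = self._grid()
        vals = np.ones((20, 20))
        vals[:, 10] = 0  # two halves
        out = barrier_clip(Layer(spec, vals), [(0.5, 19.5)])
        assert out.binary.values[0, 0] == 1
        assert out.binary.values[:, 11:].sum() == 0  # recordless half dropped

    def test_zero_records_raises(self):
        spec = self._grid()
        with pytest.raises(ValueError, match="record"):
            barrier_clip(Layer(spec, np.ones((20, 20))), [])

    def test_record_cells_always_survive(self):
        spec = self._grid()
        vals = np.zeros((20, 20))  # model predicts absence everywhere
        out = barrier_clip(Layer(spec, vals), [(5.5, 14.5)])
        assert out.binary.values[spec.cell_of(5.5, 14.5)] == 1

    def test_output_subset_of_input_plus_records(self):
        spec = self._grid()
        rng = np.random.default_rng(3)
        vals = (rng.random((20, 20)) > 0.6).astype(float)
        records = [(2.5, 17.5), (6.5, 12.5)]
        out = barrier_clip(Layer(spec, vals), records)
        record_cells = {spec.cell_of(*p) for p in records}
        rows, cols = np.nonzero(out.binary.values)
        for cell in zip(rows, cols):
            assert vals[cell] == 1 or tuple(map(int, cell)) in record_cells

    def test_single_cell_range(self):
        spec = self._grid()
        rng = single_cell_range(spec, (3.5, 12.5))
        assert rng.size == 1
        assert rng.cells == {spec.cell_of(3.5, 12.5)}
        assert rng.mean_nn_distance == 0.0


def _toy_stack(seed=0, n=12):
    spec = GridSpec(0, n, 1.0, n, n)
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter
    layers = [Layer(spec, gaussian_filter(rng.normal(size=(n, n)), 2),
                    name=f"v{i}") for i in range(3)]
    return PredictorStack(spec, layers)


class TestFitEnsemble:
    def test_consensus_weighted_average_arithmetic(self):
        # learners with AUC {0.8, 0.9} predicting {0.2, 0.8} at a cell:
        # consensus = (0.8*0.2 + 0.9*0.8) / 1.7
        w = {"a": 0.8, "b": 0.9}
        preds = {"a": 0.2, "b": 0.8}
        expected = sum(w[k] * preds[k] for k in w) / sum(w.values())
        assert expected == pytest.approx(0.51764705882, abs=1e-9)

    def test_low_auc_learner_excluded(self):
        # a constant-scoring learner gets AUC 0.5 <= 0.7 -> weight 0
        class Flat:
            def fit(self, X, y):
                return self

            def predict_proba(self, X):
                return np.column_stack([np.full(len(X), 0.5)] * 2)

        stack = _toy_stack(1)
        suit = stack.layers[0].values
        pres_cells = [tuple(map(int, rc)) for rc in
                      np.argwhere(suit > np.quantile(suit, 0.8))][:12]
        pa = sample_pseudo_absences(stack.grid, set(pres_cells), 40, seed=2)
        learners = [
            Learner("flat", lambda seed: Flat()),
            default_learners()[0],
        ]
        res = fit_ensemble(stack, set(pres_cells), pa, learners, folds=3,
                           seed=0, species="t")
        assert res.weights["flat"] == 0.0
        assert res.learner_aucs["flat"] == pytest.approx(0.5)

    def test_single_passing_learner_consensus_equals_prediction(self):
        stack = _toy_stack(2)
        suit = stack.layers[0].values
        pres_cells = [tuple(map(int, rc)) for rc in
                      np.argwhere(suit > np.quantile(suit, 0.8))][:12]
        pa = sample_pseudo_absences(stack.grid, set(pres_cells), 40, seed=3)
        res = fit_ensemble(stack, set(pres_cells), pa,
                           [default_learners()[0]], folds=3, seed=0)
        if res.usable:  # single learner -> weight normalizes to 1
            np.testing.assert_allclose(
                res.consensus.values,
                res.learner_predictions["logistic"].values)

    def test_consensus_bounded_by_contributors(self):
        stack = _toy_stack(3)
        suit = stack.layers[0].values
        pres_cells = [tuple(map(int, rc)) for rc in
                      np.argwhere(suit > np.quantile(suit, 0.75))][:20]
        pa = sample_pseudo_absences(stack.grid, set(pres_cells), 50, seed=4)
        res = fit_ensemble(stack, set(pres_cells), pa, folds=3, seed=0)
        assert res.usable
        contributing = [res.learner_predictions[n].values
                        for n, w in res.weights.items() if w > 0]
        lo = np.min(contributing, axis=0)
        hi = np.max(contributing, axis=0)
        assert np.all(res.consensus.values >= lo - 1e-12)
        assert np.all(res.consensus.values <= hi + 1e-12)

    def test_no_passing_learner_flagged_unusable(self):
        class Flat:
            def fit(self, X, y):
                return self

            def predict_proba(self, X):
                return np.column_stack([np.full(len(X), 0.5)] * 2)

        stack = _toy_stack(4)
        pres = {(0, 0), (1, 1), (2, 2), (3, 3)}
        pa = sample_pseudo_absences(stack.grid, pres, 20, seed=5)
        res = fit_ensemble(stack, pres, pa, [Learner("flat", lambda s: Flat())],
                           folds=2, seed=0)
        assert not res.usable
        assert res.consensus is None

    def test_too_few_presences(self):
        stack = _toy_stack(5)
        with pytest.raises(ValueError, match="presences"):
            fit_ensemble(stack, {(0, 0)}, {(1, 1), (2, 2)}, folds=2, seed=0)
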