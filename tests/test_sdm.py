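"""Ensemble SDM machinery: pseudo-absences, AUC, weighting, jackknife,
Jenks breaks, thresholding, binary-map accuracy — each against an
independent oracle where one exists."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corridorscape import sdm as sdm_mod
from corridorscape.raster import CovariateStack
from corridorscape.sdm import (
    LearnerSpec,
    auc_roc,
    binary_map_accuracy,
    fit_ensemble,
    jackknife_importance,
    jenks_breaks,
    max_sens_spec_threshold,
    predict_suitability,
    sample_pseudo_absences,
)
from tests.conftest import make_grid

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def auc_pair_counting(scores, labels):
    """Brute force: count positive-negative pairs, ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def jenks_exhaustive(values, k):
    """Search all ordered partitions of the sorted values into k classes."""
    x = sorted(values)
    n = len(x)

    def ssd(chunk):
        m = sum(chunk) / len(chunk)
        return sum((v - m) ** 2 for v in chunk)

    best_cost, best_breaks = float("inf"), None
    for cuts in combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        cost = sum(ssd(x[a:b]) for a, b in zip(bounds, bounds[1:]))
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_breaks = [x[c - 1] for c in cuts]
    return best_cost, best_breaks


def threshold_exhaustive(scores, labels):
    """Scan every candidate cut; return (best J, set of optimal thresholds)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    cands = (uniq[:-1] + uniq[1:]) / 2
    best_j, best_ts = -np.inf, []
    for t in cands:
        pred = scores >= t
        j = (pred & (labels == 1)).sum() / (labels == 1).sum() + (
            ~pred & (labels == 0)
        ).sum() / (labels == 0).sum()
        if j > best_j + 1e-12:
            best_j, best_ts = j, [t]
        elif abs(j - best_j) <= 1e-12:
            best_ts.append(t)
    return best_j, best_ts


# ---------------------------------------------------------------------------
# pseudo-absences
# ---------------------------------------------------------------------------


class TestPseudoAbsences:
    def test_n_equals_all_eligible_returns_eligible_set(self):
        bg = make_grid(np.ones((4, 4)))
        pres = pd.DataFrame({"row": [0, 1], "col": [0, 1], "x": [0.5, 1.5], "y": [3.5, 2.5]})
        out = sample_pseudo_absences(bg, pres, n=14, seed=0)
        got = set(zip(out["row"], out["col"]))
        expected = {(r, c) for r in range(4) for c in range(4)} - {(0, 0), (1, 1)}
        assert got == expected

    def test_never_on_presence_cells(self, rng):
        bg = make_grid(np.ones((10, 10)))
        pres = pd.DataFrame({"row": rng.integers(0, 10, 20), "col": rng.integers(0, 10, 20)})
        pres["x"] = pres["col"] + 0.5
        pres["y"] = 10 - pres["row"] - 0.5
        out = sample_pseudo_absences(bg, pres, n=50, seed=1)
        assert not (set(zip(out["row"], out["col"])) & set(zip(pres["row"], pres["col"])))

    def test_too_few_eligible_cells_raises(self):
        bg = make_grid(np.ones((3, 3)))
        pres = pd.DataFrame({"row": [0], "col": [0]})
        with pytest.raises(ValueError, match="eligible"):
            sample_pseudo_absences(bg, pres, n=9, seed=0)

    def test_default_n_is_1000(self):
        import inspect

        assert inspect.signature(sample_pseudo_absences).parameters["n"].default == 1000


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


class TestAUC:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_roc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_roc([0.1, 0.2], [1, 1])

    def test_example_matches_pair_counting(self):
        scores, labels = [0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]
        assert auc_roc(scores, labels) == pytest.approx(auc_pair_counting(scores, labels))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_random_sets_match_pair_counting_and_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # ties likely
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        ours = auc_roc(scores, labels)
        assert ours == pytest.approx(auc_pair_counting(scores, labels))
        assert ours == pytest.approx(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


def _separable_data(rng, n=60):
    """One informative covariate, one noise covariate."""
    grid_info = make_grid(np.tile(np.linspace(0, 1, 10), (10, 1)))
    grid_noise = make_grid(rng.normal(size=(10, 10)))
    stack = CovariateStack(names=["info", "noise"],
                           grids={"info": grid_info, "noise": grid_noise})
    rows = rng.integers(0, 10, n)
    cols_hi = rng.integers(5, 10, n // 2)
    cols_lo = rng.integers(0, 5, n - n // 2)
    pres = pd.DataFrame({"row": rows[: n // 2], "col": cols_hi})
    absn = pd.DataFrame({"row": rows[n // 2:], "col": cols_lo})
    return pres, absn, stack


def _constant_learner(name="const"):
    class Const:
        def fit(self, X, y):
            return self

        def predict(self, X):
            return np.full(X.shape[0], 0.5)

    return LearnerSpec(name, lambda seed: Const())


def _threshold_learner(name="logit"):
    from sklearn.linear_model import LogisticRegression

    return LearnerSpec(
        name, lambda seed: sdm_mod._SkScorer(LogisticRegression(max_iter=200))
    )


class TestEnsemble:
    def test_equal_mean_auc_gives_equal_weights(self, rng):
        pres, absn, stack = _separable_data(rng)
        model = fit_ensemble(pres, absn, stack,
                             [_threshold_learner("logit_a"), _threshold_learner("logit_b")],
                             replications=3, seed=0)
        assert model.weights["logit_a"] == pytest.approx(model.weights["logit_b"], abs=0.05)
        assert sum(model.weights.values()) == pytest.approx(1.0)

    def test_constant_learner_gets_auc_half_and_lower_weight(self, rng):
        pres, absn, stack = _separable_data(rng)
        model = fit_ensemble(pres, absn, stack,
                             [_threshold_learner(), _constant_learner()],
                             replications=4, seed=0)
        assert model.mean_auc["const"] == pytest.approx(0.5)
        assert model.mean_auc["logit"] > 0.9
        assert model.weights["logit"] > model.weights["const"]

    def test_failing_learner_excluded_not_fatal(self, rng):
        class Boom:
            def fit(self, X, y):
                raise RuntimeError("nope")

        pres, absn, stack = _separable_data(rng)
        model = fit_ensemble(
            pres, absn, stack,
            [_threshold_learner(), LearnerSpec("boom", lambda s: Boom())],
            replications=3, seed=0,
        )
        assert np.isnan(model.auc_table.loc["boom"]).all()
        assert model.weights["boom"] == 0.0

    def test_prediction_is_convex_combination(self, rng):
        pres, absn, stack = _separable_data(rng)
        model = fit_ensemble(pres, absn, stack,
                             [_threshold_learner(), _constant_learner()],
                             replications=3, seed=0)
        surf = predict_suitability(model, stack)
        v = surf.grid.valid_values()
        assert np.all(v >= 0) and np.all(v <= 1)

    def test_fixed_weights_arithmetic(self):
        """Learners predicting 0.2 and 0.8 everywhere at weights (0.5, 0.5)
        give exactly 0.5 everywhere; a single learner at weight 1 reproduces
        its own mean prediction."""

        def const_learner(name, value):
            class C:
                def fit(self, X, y):
                    return self

                def predict(self, X):
                    return np.full(X.shape[0], value)

            return LearnerSpec(name, lambda s: C())

        grid = make_grid(np.zeros((5, 5)))
        stack = CovariateStack(names=["z"], grids={"z": grid})
        model = sdm_mod.EnsembleModel(
            learner_names=["lo", "hi"],
            fitted={"lo": [const_learner("lo", 0.2).factory(0)],
                    "hi": [const_learner("hi", 0.8).factory(0)]},
            auc_table=pd.DataFrame([[0.7], [0.7]], index=["lo", "hi"]),
            weights={"lo": 0.5, "hi": 0.5},
            covariate_names=["z"], replications=1, train_fraction=0.75,
        )
        surf = predict_suitability(model, stack)
        assert np.allclose(surf.grid.values, 0.5)
        model.weights = {"lo": 1.0, "hi": 0.0}
        assert np.allclose(predict_suitability(model, stack).grid.values, 0.2)

    def test_missing_covariate_named_in_error(self, rng):
        pres, absn, stack = _separable_data(rng)
        model = fit_ensemble(pres, absn, stack,
                             [_threshold_learner(), _constant_learner()],
                             replications=2, seed=0)
        with pytest.raises(ValueError, match="info"):
            predict_suitability(model, stack.subset(["noise"]))

    def test_weighted_prediction_invariant_to_learner_order(self, rng):
        pres, absn, stack = _separable_data(rng)
        a = fit_ensemble(pres, absn, stack,
                         [_threshold_learner(), _constant_learner()],
                         replications=3, seed=0)
        b = fit_ensemble(pres, absn, stack,
                         [_constant_learner(), _threshold_learner()],
                         replications=3, seed=0)
        sa = predict_suitability(a, stack).grid.values
        sb = predict_suitability(b, stack).grid.values
        assert np.allclose(sa, sb, atol=1e-10)


class TestJackknife:
    def test_noise_covariate_near_zero_informative_first(self, rng):
        pres, absn, stack = _separable_data(rng, n=120)
        imp = jackknife_importance(pres, absn, stack,
                                   [_threshold_learner(), _constant_learner()],
                                   replications=3, seed=0)
        assert sum(imp.values()) == pytest.approx(100.0)
        assert imp["info"] > imp["noise"]
        assert imp["noise"] < 20.0

    def test_all_zero_importances_fall_back_to_uniform(self, rng):
        grid_a = make_grid(rng.normal(size=(10, 10)))
        grid_b = make_grid(rng.normal(size=(10, 10)))
        stack = CovariateStack(names=["a", "b"], grids={"a": grid_a, "b": grid_b})
        pres = pd.DataFrame({"row": rng.integers(0, 10, 30), "col": rng.integers(0, 10, 30)})
        absn = pd.DataFrame({"row": rng.integers(0, 10, 30), "col": rng.integers(0, 10, 30)})
        with pytest.warns(UserWarning, match="uniform"):
            imp = jackknife_importance(pres, absn, stack,
                                       [_constant_learner("c1"), _constant_learner("c2")],
                                       replications=2, seed=0)
        assert imp == {"a": 50.0, "b": 50.0}


# ---------------------------------------------------------------------------
# Jenks
# ---------------------------------------------------------------------------


class TestJenks:
    def test_separated_clusters(self):
        assert jenks_breaks([1, 2, 101, 102], k=2) == [2.0]

    def test_identical_values_raise(self):
        with pytest.raises(ValueError, match="distinct"):
            jenks_breaks([5.0] * 10, k=2)

    def test_k_below_two_raises(self):
        with pytest.raises(ValueError, match="k must be"):
            jenks_breaks([1, 2, 3], k=1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_partition_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        values = np.round(rng.uniform(0, 10, n), 2)
        if np.unique(values).size < 3:
            values = values + np.arange(n) * 0.01
        breaks = jenks_breaks(values, k=3)
        best_cost, _ = jenks_exhaustive(values.tolist(), 3)
        # score the DP's breaks with the oracle's cost function
        classes = np.searchsorted(np.asarray(breaks), np.sort(values), side="left")
        cost = sum(
            ((np.sort(values)[classes == c] - np.sort(values)[classes == c].mean()) ** 2).sum()
            for c in np.unique(classes)
        )
        assert cost == pytest.approx(best_cost, abs=1e-9)


# ---------------------------------------------------------------------------
# threshold + binary accuracy
# ---------------------------------------------------------------------------


class TestThreshold:
    def test_separated_classes_lowest_midpoint(self):
        t = max_sens_spec_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.5)  # lowest optimal midpoint

    def test_unique_argmax_example(self):
        assert max_sens_spec_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1]) == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            max_sens_spec_threshold([0.1, 0.9], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_random_sets_match_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        scores = rng.choice(np.round(np.linspace(0, 1, 11), 2), size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        if np.unique(scores).size < 2:
            scores[0] = 1 - scores[0] or 0.5
        t = max_sens_spec_threshold(scores, labels)
        best_j, best_ts = threshold_exhaustive(scores, labels)
        assert t == pytest.approx(min(best_ts))


class TestBinaryMapAccuracy:
    def test_perfect_and_inverted_maps(self):
        binary = make_grid((np.arange(16).reshape(4, 4) >= 8).astype(float))
        pts = pd.DataFrame({
            "row": [0, 1, 2, 3], "col": [0, 1, 2, 3],
            "x": [0.5, 1.5, 2.5, 3.5], "y": [3.5, 2.5, 1.5, 0.5],
            "presence": [0, 0, 1, 1],
        })
        assert binary_map_accuracy(binary, pts) == 100.0
        inverted = binary.copy_with(1.0 - binary.values)
        assert binary_map_accuracy(inverted, pts) == 0.0

    def test_hand_built_five_point_example(self):
        binary = make_grid([[1.0, 0.0], [0.0, 1.0]])
        pts = pd.DataFrame({
            "row": [0, 0, 1, 1, 0], "col": [0, 1, 0, 1, 0],
            "x": [0.5, 1.5, 0.5, 1.5, 0.5], "y": [1.5, 1.5, 0.5, 0.5, 1.5],
            "presence": [1, 1, 0, 1, 0],
        })
        # matches: (0,0)->1==1, (0,1)->0!=1, (1,0)->0==0, (1,1)->1==1, (0,0)->1!=0
        assert binary_map_accuracy(binary, pts) == pytest.approx(60.0)

    def test_outside_points_excluded_with_warning(self):
        binary = make_grid(np.ones((2, 2)))
        pts = pd.DataFrame({"x": [0.5, 9.0], "y": [1.5, 9.0], "presence": [1, 1]})
        with pytest.warns(UserWarning, match="outside"):
            acc = binary_map_accuracy(binary, pts)
        assert acc == 100.0
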