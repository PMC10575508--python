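"""Ensemble habitat-suitability modelling.

Presence-only species distribution modelling with pseudo-absences: repeated
stratified train/test splits, per-learner AUC on held-out points, weighted
averaging of learner predictions with weights proportional to mean test AUC,
jackknife (leave-one-covariate-out) variable importance, Jenks natural-breaks
classing into high/moderate/marginal suitability, and the
max(sensitivity+specificity) threshold for binarization.

The ensemble machinery here is self-contained; the individual learners are
pluggable scorers satisfying :class:`LearnerSpec`'s fit/predict contract (the
four registered defaults are backed by scikit-learn estimators).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from corridorscape.raster import CovariateStack, RasterGrid

__all__ = [
    "LearnerSpec",
    "EnsembleModel",
    "SuitabilitySurface",
    "default_learners",
    "sample_pseudo_absences",
    "auc_roc",
    "fit_ensemble",
    "predict_suitability",
    "jackknife_importance",
    "jenks_breaks",
    "classify_suitability",
    "max_sens_spec_threshold",
    "binary_map_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass
class LearnerSpec:
    """Pluggable learner: ``factory(seed)`` returns an object with
    ``fit(X, y)`` and ``predict(X) -> scores in [0, 1]``."""

    name: str
    factory: Callable[[int], "object"]
    hyperparameters: dict = field(default_factory=dict)


class _SkScorer:
    """Adapts a scikit-learn classifier (predict_proba) to the scorer contract."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def predict(self, X):
        proba = self.estimator.predict_proba(X)[:, 1]
        return np.clip(proba, 0.0, 1.0)


def default_learners(fast: bool = False) -> list[LearnerSpec]:
    """The four registered learner families: a maximum-entropy-style
    regularized logistic scorer, boosted shallow trees, an additive spline
    scorer, and bagged decision trees (a random forest).

    ``fast=True`` returns just the two cheap learners (logistic and additive
    splines) for large replicated experiments.
    """
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import SplineTransformer, StandardScaler

    def maxent_like(seed: int):
        return _SkScorer(
            make_pipeline(StandardScaler(), LogisticRegression(C=1.0, max_iter=1000))
        )

    def additive(seed: int):
        return _SkScorer(
            make_pipeline(
                StandardScaler(),
                SplineTransformer(n_knots=5, degree=3),
                LogisticRegression(C=1.0, max_iter=1000),
            )
        )

    def boosted(seed: int):
        return _SkScorer(
            GradientBoostingClassifier(
                n_estimators=100, max_depth=2, learning_rate=0.1, random_state=seed
            )
        )

    def forest(seed: int):
        return _SkScorer(
            RandomForestClassifier(n_estimators=100, min_samples_leaf=5, random_state=seed)
        )

    specs = [
        LearnerSpec("maxent_like", maxent_like),
        LearnerSpec("additive", additive),
    ]
    if not fast:
        specs += [LearnerSpec("gbm", boosted), LearnerSpec("rf", forest)]
    return specs


@dataclass
class EnsembleModel:
    """Fitted ensemble: one fitted scorer per (learner, replication), the
    learner x replication AUC table, and AUC-proportional weights."""

    learner_names: list[str]
    fitted: dict[str, list[object]]  # learner -> one fitted scorer per replication
    auc_table: pd.DataFrame  # rows learners, cols replications
    weights: dict[str, float]
    covariate_names: list[str]
    replications: int
    train_fraction: float

    @property
    def mean_auc(self) -> dict[str, float]:
        return self.auc_table.mean(axis=1, skipna=True).to_dict()

    @property
    def weighted_mean_auc(self) -> float:
        means = self.auc_table.mean(axis=1, skipna=True)
        return float(sum(self.weights[n] * means[n] for n in self.learner_names))


@dataclass
class SuitabilitySurface:
    """Continuous suitability in [0, 1] plus optional 3-class and binary views."""

    grid: RasterGrid
    classes: RasterGrid | None = None
    class_breaks: tuple[float, ...] | None = None
    threshold: float | None = None

    def binary(self) -> RasterGrid:
        if self.threshold is None:
            raise ValueError("no binarization threshold set")
        valid = self.grid.valid_mask()
        out = np.full(self.grid.shape, self.grid.nodata)
        out[valid] = (self.grid.values[valid] >= self.threshold).astype(float)
        return self.grid.copy_with(out)


# ---------------------------------------------------------------------------
# Pseudo-absences
# ---------------------------------------------------------------------------


def sample_pseudo_absences(
    background: RasterGrid,
    presences: pd.DataFrame,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw ``n`` background cells uniformly without replacement, excluding
    cells that contain a presence point. Default n follows the study design
    of 1000 pseudo-absences."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = (background.values > 0) & background.valid_mask()
    pres_cells = _point_cells(background, presences)
    eligible[pres_cells[:, 0], pres_cells[:, 1]] = False
    rows, cols = np.nonzero(eligible)
    if rows.size < n:
        raise ValueError(f"only {rows.size} eligible background cells for n={n}")
    idx = rng.choice(rows.size, size=n, replace=False)
    idx = np.sort(idx)
    rr, cc = rows[idx], cols[idx]
    x = background.origin[0] + (cc + 0.5) * background.cellsize
    y = background.origin[1] - (rr + 0.5) * background.cellsize
    return pd.DataFrame({"x": x, "y": y, "row": rr, "col": cc})


def _point_cells(grid: RasterGrid, points: pd.DataFrame) -> np.ndarray:
    """(row, col) per point; uses explicit row/col columns when present."""
    if {"row", "col"} <= set(points.columns):
        return points[["row", "col"]].to_numpy(dtype=int)
    cols = np.floor((points["x"].to_numpy() - grid.origin[0]) / grid.cellsize).astype(int)
    rows = np.floor((grid.origin[1] - points["y"].to_numpy()) / grid.cellsize).astype(int)
    return np.column_stack([rows, cols])


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def auc_roc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random positive outscores a random
    negative, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Ensemble fitting and prediction
# ---------------------------------------------------------------------------


def _stratified_split(
    n_pos: int, n_neg: int, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean train masks for positives and negatives, preserving the ratio."""
    def mask(n: int) -> np.ndarray:
        k = int(round(train_fraction * n))
        k = min(max(k, 1), n - 1)
        m = np.zeros(n, dtype=bool)
        m[rng.permutation(n)[:k]] = True
        return m

    return mask(n_pos), mask(n_neg)


def fit_ensemble(
    presences: pd.DataFrame,
    absences: pd.DataFrame,
    stack: CovariateStack,
    learners: Sequence[LearnerSpec] | None = None,
    replications: int = 10,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> EnsembleModel:
    """Fit the accuracy-weighted ensemble.

    Per replication: a stratified split keeps ``train_fraction`` of the
    presences and of the absences for training; every learner is fitted on
    the training rows and scored by AUC on the held-out rows. Weights are the
    learner mean AUCs normalized to sum to one. A learner that raises on one
    replication is logged and excluded from its own mean.
    """
    if learners is None:
        learners = default_learners()
    if len(learners) < 2:
        raise ValueError("ensemble requires at least 2 learners")
    if len({sp.name for sp in learners}) != len(learners):
        raise ValueError("learner names must be unique")
    grid = stack.template
    pres_cells = _point_cells(grid, presences)
    abs_cells = _point_cells(grid, absences)
    X_pos = stack.rows_at(pres_cells[:, 0], pres_cells[:, 1])
    X_neg = stack.rows_at(abs_cells[:, 0], abs_cells[:, 1])
    if X_pos.shape[0] + X_neg.shape[0] < 20:
        raise ValueError("need at least 20 labelled points to fit the ensemble")

    rng = np.random.default_rng((int(seed), 11))
    fitted: dict[str, list[object]] = {sp.name: [] for sp in learners}
    auc = np.full((len(learners), replications), np.nan)
    for rep in range(replications):
        m_pos, m_neg = _stratified_split(X_pos.shape[0], X_neg.shape[0], train_fraction, rng)
        X_train = np.vstack([X_pos[m_pos], X_neg[m_neg]])
        y_train = np.concatenate([np.ones(m_pos.sum()), np.zeros(m_neg.sum())])
        X_test = np.vstack([X_pos[~m_pos], X_neg[~m_neg]])
        y_test = np.concatenate([np.ones((~m_pos).sum()), np.zeros((~m_neg).sum())])
        for li, sp in enumerate(learners):
            learner_seed = int(rng.integers(2**31 - 1))
            try:
                scorer = sp.factory(learner_seed)
                scorer.fit(X_train, y_train)
                auc[li, rep] = auc_roc(scorer.predict(X_test), y_test)
                fitted[sp.name].append(scorer)
            except Exception as exc:  # noqa: BLE001 - learner plug-ins may fail arbitrarily
                logger.warning("learner %s failed on replication %d: %s", sp.name, rep, exc)

    names = [sp.name for sp in learners]
    auc_table = pd.DataFrame(auc, index=names, columns=range(replications))
    means = auc_table.mean(axis=1, skipna=True).fillna(0.0)
    total = means.sum()
    if total <= 0:
        raise RuntimeError("all learners failed on all replications")
    weights = (means / total).to_dict()
    return EnsembleModel(
        learner_names=names,
        fitted=fitted,
        auc_table=auc_table,
        weights=weights,
        covariate_names=list(stack.names),
        replications=replications,
        train_fraction=train_fraction,
    )


def predict_suitability(model: EnsembleModel, stack: CovariateStack) -> SuitabilitySurface:
    """Weighted average, over learners, of each learner's mean prediction
    across replications; nodata propagated from the stack."""
    missing = [n for n in model.covariate_names if n not in stack]
    if missing:
        raise ValueError(f"stack missing model covariates: {missing}")
    stack = stack.subset(model.covariate_names)
    mask = stack.joint_valid_mask()
    X = stack.to_matrix(mask)
    pred = np.zeros(X.shape[0])
    for name in model.learner_names:
        scorers = model.fitted[name]
        if not scorers:
            continue
        learner_mean = np.mean([s.predict(X) for s in scorers], axis=0)
        pred += model.weights[name] * learner_mean
    grid = stack.template
    out = np.full(grid.shape, grid.nodata)
    out[mask] = np.clip(pred, 0.0, 1.0)
    return SuitabilitySurface(grid=grid.copy_with(out))


# ---------------------------------------------------------------------------
# Jackknife importance
# ---------------------------------------------------------------------------


def jackknife_importance(
    presences: pd.DataFrame,
    absences: pd.DataFrame,
    stack: CovariateStack,
    learners: Sequence[LearnerSpec] | None = None,
    replications: int = 5,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> dict[str, float]:
    """Leave-one-covariate-out importance as percent contributions.

    For each covariate the ensemble is refitted without it; the raw
    importance is the drop in weighted mean test AUC (floored at 0), and the
    raw values are normalized to sum to 100%.
    """
    if len(stack) < 2:
        raise ValueError("jackknife requires at least 2 covariates")
    full = fit_ensemble(
        presences, absences, stack, learners, replications, train_fraction, seed
    ).weighted_mean_auc
    raw: dict[str, float] = {}
    for name in stack.names:
        reduced = stack.subset([n for n in stack.names if n != name])
        auc_wo = fit_ensemble(
            presences, absences, reduced, learners, replications, train_fraction, seed
        ).weighted_mean_auc
        raw[name] = max(0.0, full - auc_wo)
    total = sum(raw.values())
    if total == 0:
        warnings.warn("all jackknife importances are zero; returning uniform contributions",
                      stacklevel=2)
        return {n: 100.0 / len(raw) for n in raw}
    return {n: 100.0 * v / total for n, v in raw.items()}


# ---------------------------------------------------------------------------
# Jenks natural breaks
# ---------------------------------------------------------------------------


def jenks_breaks(values: Sequence[float], k: int = 3) -> list[float]:
    """Exact Jenks natural-breaks classification.

    Dynamic program minimizing the total within-class sum of squared
    deviations over all partitions of the sorted values into ``k`` contiguous
    classes. Returns the k-1 upper boundaries of the lower classes; class
    membership is then (-inf, b1], (b1, b2], ..., (b_{k-1}, inf).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes")

    # prefix sums for O(1) within-class SSD of x[i:j]
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:  # cost of class x[i:j], j exclusive
        m = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                cand = cost[c - 1, i] + ssd(i, j)
                if cand < best:
                    best, arg = cand, i
            cost[c, j] = best
            split[c, j] = arg
    # recover class boundaries
    bounds = []
    j = n
    for c in range(k, 1, -1):
        i = split[c, j]
        bounds.append(x[i - 1])  # upper value of the class below the split
        j = i
    return sorted(bounds)


def classify_suitability(
    surface: SuitabilitySurface, k: int = 3, max_cells: int = 20000, seed: int = 0
) -> SuitabilitySurface:
    """Class the suitability surface into ``k`` levels by Jenks breaks
    (k=3: 1=marginal, 2=moderate, 3=high). Breaks are computed on at most
    ``max_cells`` cells (seeded subsample) to bound the O(n^2) program."""
    grid = surface.grid
    vals = grid.valid_values()
    if vals.size > max_cells:
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=max_cells, replace=False)
    breaks = jenks_breaks(vals, k)
    valid = grid.valid_mask()
    classes = np.full(grid.shape, grid.nodata)
    classes[valid] = 1.0 + np.searchsorted(np.asarray(breaks), grid.values[valid], side="left")
    return SuitabilitySurface(
        grid=grid,
        classes=grid.copy_with(classes),
        class_breaks=tuple(breaks),
        threshold=surface.threshold,
    )


# ---------------------------------------------------------------------------
# Thresholding and binary-map accuracy
# ---------------------------------------------------------------------------


def max_sens_spec_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are midpoints between adjacent sorted unique scores; ties are
    broken toward the lowest threshold. A point is classed suitable when
    score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold selection requires both classes present")
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2
    best_t, best_j = None, -np.inf
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def binary_map_accuracy(binary: RasterGrid, observations: pd.DataFrame) -> float:
    """Percent of observation points whose presence flag (column ``presence``)
    matches the binary map class at their cell; points outside the grid are
    excluded with a warning."""
    pts = observations
    cells = _point_cells(binary, pts)
    inside = (
        (cells[:, 0] >= 0)
        & (cells[:, 0] < binary.nrows)
        & (cells[:, 1] >= 0)
        & (cells[:, 1] < binary.ncols)
    )
    if not inside.all():
        warnings.warn(f"{(~inside).sum()} observation points fall outside the grid; excluded",
                      stacklevel=2)
    cells = cells[inside]
    obs = pts.loc[inside, "presence"].to_numpy().astype(int)
    pred = (binary.values[cells[:, 0], cells[:, 1]] > 0).astype(int)
    if obs.size == 0:
        raise ValueError("no observation points inside the grid")
    return float(100.0 * (obs == pred).mean())
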