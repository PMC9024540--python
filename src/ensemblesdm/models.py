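"""Presence/pseudo-absence datasets and the nine-algorithm model suite.

The suite mirrors the classic biomod2 lineup: GLM, GBM, GAM, CTA, ANN, SRE,
FDA, RF and MAXENT.  Eight are standard learners from scikit-learn behind a
single scorer contract (predict probabilities in [0, 1] from a predictor
table); the surface range envelope (SRE) is implemented natively as the
rectilinear envelope between the q and 1-q presence quantiles per predictor.
MAXENT is approximated as an L1-regularized logistic model on linear plus
quadratic features.

Pseudo-absences are drawn uniformly among valid cells not holding a presence;
they are down-weighted at fit time so total absence weight equals total
presence weight (the "prevalence 0.5" convention), for learners that accept
sample weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import has_fit_parameter

from ._random import subseed
from .evaluation import EvaluationResult, tss_optimize
from .occurrences import OccurrenceSet
from .raster import RasterStack

log = logging.getLogger(__name__)

ALGORITHMS = ("GLM", "GBM", "GAM", "CTA", "ANN", "SRE", "FDA", "RF", "MAXENT")


def sample_pseudo_absences(stack: RasterStack, occ: OccurrenceSet,
                           n: int = 10_000, seed: int = 0) -> np.ndarray:
    """Uniform pseudo-absence cells (without replacement) avoiding presences.

    Returns an (n, 2) lon/lat array at cell centers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = stack.valid_mask.copy()
    prow, pcol = stack.georef.cell_index(occ.lons, occ.lats)
    inside = (prow >= 0) & (prow < mask.shape[0]) & (pcol >= 0) & (pcol < mask.shape[1])
    mask[prow[inside], pcol[inside]] = False
    rows, cols = np.nonzero(mask)
    if rows.size < n:
        raise ValueError(f"requested {n} pseudo-absences but only {rows.size} "
                         f"eligible cells ({int(stack.valid_mask.sum())} valid, "
                         f"{len(occ)} presences)")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n, replace=False)
    lons, lats = stack.georef.cell_centers(rows[pick], cols[pick])
    return np.column_stack([lons, lats])


@dataclass
class ModelingDataset:
    """Predictor table + labels + weights + per-repetition train/val splits."""

    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray
    splits: list[np.ndarray] = field(default_factory=list)  # boolean train masks

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.X.to_numpy()).all():
            raise ValueError("predictor table contains missing values")
        if len(self.X) != len(self.y) or len(self.y) != len(self.weights):
            raise ValueError("X, y and weights must align")

    @property
    def n_reps(self) -> int:
        return len(self.splits)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def build_dataset(stack: RasterStack, presences: OccurrenceSet,
                  absence_points: np.ndarray,
                  layer_names: Sequence[str] | None = None) -> ModelingDataset:
    """Assemble the modeling table from presence and pseudo-absence points.

    Pseudo-absence weights are scaled so both classes carry equal total
    weight.
    """
    names = list(layer_names) if layer_names is not None else list(stack.names)
    Xp = stack.values_at(presences.lons, presences.lats, names)
    Xa = stack.values_at(absence_points[:, 0], absence_points[:, 1], names)
    X = pd.DataFrame(np.vstack([Xp, Xa]), columns=names)
    y = np.concatenate([np.ones(len(Xp), dtype=int), np.zeros(len(Xa), dtype=int)])
    w = np.ones(len(y))
    if len(Xa):
        w[y == 0] = len(Xp) / len(Xa)
    keep = np.isfinite(X.to_numpy()).all(axis=1)
    return ModelingDataset(X.loc[keep].reset_index(drop=True), y[keep], w[keep])


def make_splits(dataset: ModelingDataset, train_frac: float = 0.8,
                reps: int = 3, seed: int = 0) -> list[np.ndarray]:
    """Stratified random train/validation assignments, one per repetition."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    counts = np.bincount(dataset.y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 points to split")
    splitter = StratifiedShuffleSplit(
        n_splits=reps, train_size=train_frac,
        random_state=int(subseed(seed, "splits").integers(2**31)))
    splits = []
    for train_idx, _ in splitter.split(dataset.X, dataset.y):
        mask = np.zeros(len(dataset.y), dtype=bool)
        mask[train_idx] = True
        splits.append(mask)
    dataset.splits = splits
    return splits


class SurfaceRangeEnvelope:
    """Rectilinear climatic envelope between presence quantiles.

    fit() learns per-predictor [q, 1-q] presence quantiles (default
    q = 0.025); predict_proba is 1 inside the envelope on every predictor,
    else 0.
    """

    def __init__(self, quantile: float = 0.025):
        if not 0 <= quantile < 0.5:
            raise ValueError("quantile must be in [0, 0.5)")
        self.quantile = quantile

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        pres = X[y == 1]
        if len(pres) == 0:
            raise ValueError("SRE needs at least one presence")
        self.lower_ = np.quantile(pres, self.quantile, axis=0)
        self.upper_ = np.quantile(pres, 1 - self.quantile, axis=0)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        inside = ((X >= self.lower_) & (X <= self.upper_)).all(axis=1)
        p1 = inside.astype(float)
        return np.column_stack([1 - p1, p1])


def _make_estimator(algorithm: str, random_state: int):
    if algorithm == "GLM":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", LogisticRegression(C=np.inf, max_iter=2000))])
    if algorithm == "GBM":
        return GradientBoostingClassifier(n_estimators=100, max_depth=3,
                                          learning_rate=0.1,
                                          random_state=random_state)
    if algorithm == "GAM":
        return Pipeline([("spline", SplineTransformer(n_knots=5, degree=3)),
                         ("clf", LogisticRegression(C=10.0, max_iter=2000))])
    if algorithm == "CTA":
        return DecisionTreeClassifier(max_depth=8, min_samples_leaf=5,
                                      random_state=random_state)
    if algorithm == "ANN":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", MLPClassifier(hidden_layer_sizes=(8,),
                                               max_iter=1000, alpha=1e-3,
                                               random_state=random_state))])
    if algorithm == "SRE":
        return SurfaceRangeEnvelope()
    if algorithm == "FDA":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if algorithm == "RF":
        return RandomForestClassifier(n_estimators=200, min_samples_leaf=2,
                                      random_state=random_state)
    if algorithm == "MAXENT":
        return Pipeline([("scale", StandardScaler()),
                         ("quad", PolynomialFeatures(degree=2, include_bias=False)),
                         ("clf", LogisticRegression(l1_ratio=1.0, C=1.0,
                                                    solver="liblinear",
                                                    random_state=random_state))])
    raise ValueError(f"unknown algorithm '{algorithm}'; choose from {ALGORITHMS}")


def _fit_with_weights(est, X, y, w):
    """Fit passing sample_weight where the estimator supports it."""
    if isinstance(est, Pipeline):
        final = est.steps[-1]
        if has_fit_parameter(final[1], "sample_weight"):
            est.fit(X, y, **{f"{final[0]}__sample_weight": w})
            return est, True
        est.fit(X, y)
        return est, False
    if isinstance(est, SurfaceRangeEnvelope) or has_fit_parameter(est, "sample_weight"):
        est.fit(X, y, sample_weight=w)
        return est, True
    est.fit(X, y)
    return est, False


@dataclass
class FittedModel:
    """One algorithm x repetition with its held-out evaluation."""

    algorithm: str
    repetition: int
    estimator: object | None
    feature_names: list[str]
    evaluation: EvaluationResult | None = None
    weighted_fit: bool = False
    failed: bool = False
    failure_reason: str | None = None

    def predict(self, X) -> np.ndarray:
        """Scorer contract: probabilities in [0, 1] for the presence class."""
        if self.failed or self.estimator is None:
            raise RuntimeError(f"model {self.algorithm} rep {self.repetition} failed")
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names]
        p = self.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]
        return np.clip(p, 0.0, 1.0)

    @property
    def tss(self) -> float:
        return self.evaluation.tss if self.evaluation else float("nan")


def fit(algorithm: str, dataset: ModelingDataset, repetition: int,
        seed: int = 0) -> FittedModel:
    """Train one algorithm on the training fold of one repetition and score
    it on the held-out fold.

    A degenerate training fold (a single class) marks the model failed
    instead of raising, so a suite run survives individual failures.
    """
    if not 1 <= repetition <= dataset.n_reps:
        raise ValueError(f"repetition {repetition} has no split (reps={dataset.n_reps})")
    train = dataset.splits[repetition - 1]
    ytr = dataset.y[train]
    model = FittedModel(algorithm, repetition, None, dataset.feature_names)
    if np.unique(ytr).size < 2:
        model.failed = True
        model.failure_reason = "training fold contains a single class"
        log.warning("%s rep %d failed: %s", algorithm, repetition, model.failure_reason)
        return model
    rs = int(subseed(seed, "fit", algorithm, repetition).integers(2**31))
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm '{algorithm}'; choose from {ALGORITHMS}")
    try:
        est = _make_estimator(algorithm, rs)
        est, weighted = _fit_with_weights(est, dataset.X[train].to_numpy(float),
                                          ytr, dataset.weights[train])
    except Exception as exc:  # noqa: BLE001 - any learner failure is recoverable
        model.failed = True
        model.failure_reason = f"{type(exc).__name__}: {exc}"
        log.warning("%s rep %d failed: %s", algorithm, repetition, model.failure_reason)
        return model
    model.estimator = est
    model.weighted_fit = weighted
    val = ~train
    model.evaluation = tss_optimize(dataset.y[val], model.predict(dataset.X[val]))
    return model


@dataclass
class ModelSuite:
    """All fitted models of one run, successes and failures."""

    models: list[FittedModel]
    failures: list[FittedModel] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)

    def scores(self) -> pd.DataFrame:
        rows = [{"algorithm": m.algorithm, "repetition": m.repetition,
                 "auc": m.evaluation.auc, "tss": m.evaluation.tss,
                 "tss_threshold": m.evaluation.tss_threshold}
                for m in self.models]
        return pd.DataFrame(rows)


def fit_suite(dataset: ModelingDataset, reps: int | None = None,
              algorithms: Sequence[str] = ALGORITHMS,
              seed: int = 0) -> ModelSuite:
    """Fit every algorithm x repetition (9 x 3 = 27 models at defaults).

    Per-model failures are collected, not propagated.
    """
    if not dataset.splits:
        make_splits(dataset, seed=seed)
    reps = reps if reps is not None else dataset.n_reps
    if reps > dataset.n_reps:
        raise ValueError(f"asked for {reps} reps but dataset has {dataset.n_reps} splits")
    ok, bad = [], []
    for rep in range(1, reps + 1):
        for algo in algorithms:
            m = fit(algo, dataset, rep, seed=seed)
            (bad if m.failed else ok).append(m)
    return ModelSuite(ok, bad)
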