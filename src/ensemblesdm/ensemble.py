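"""TSS-gated ensembles: committee averaging and weighted means, projection
onto raster stacks, pooled ensemble evaluation, and the importance table.

Only members whose held-out TSS reaches the gate (default 0.8, inclusive)
enter an ensemble.  Committee averaging binarizes each member at its own
TSS-optimal cutoff and averages the votes; the weighted mean averages the
continuous member scores with TSS-proportional weights.  Both are reported
on the conventional 0-1000 integer habitat-suitability scale (rounded
half-up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._random import subseed
from .evaluation import EvaluationResult, permutation_importance, tss_optimize
from .models import FittedModel, ModelingDataset, ModelSuite
from .raster import RasterStack

METHODS = ("committee", "weighted")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def gate_models(models: list[FittedModel], gate: float = 0.8) -> list[FittedModel]:
    return [m for m in models if not m.failed and m.evaluation is not None
            and m.evaluation.tss >= gate]


@dataclass
class Ensemble:
    """A gated set of member models with method-specific combination."""

    method: str
    members: list[FittedModel]
    weights: np.ndarray  # TSS-proportional for 'weighted'; uniform otherwise
    gate: float

    def member_scores(self, X) -> np.ndarray:
        return np.column_stack([m.predict(X) for m in self.members])

    def combine(self, scores: np.ndarray) -> np.ndarray:
        """Continuous ensemble score in [0, 1] from member scores (n, k)."""
        if self.method == "committee":
            thresholds = np.array([m.evaluation.tss_threshold for m in self.members])
            votes = (scores >= thresholds[None, :]).astype(float)
            return votes.mean(axis=1)
        return scores @ self.weights

    def predict(self, X) -> np.ndarray:
        """Ensemble score in [0, 1] at tabular predictor rows."""
        return self.combine(self.member_scores(X))

    def predict_scaled(self, X) -> np.ndarray:
        """Integer 0-1000 habitat-suitability values (half-up rounding)."""
        return _round_half_up(1000.0 * self.predict(X))


def build_ensemble(models: list[FittedModel] | ModelSuite, method: str,
                   gate: float = 0.8) -> Ensemble:
    """Assemble a TSS-gated ensemble; raises if no member passes the gate."""
    if isinstance(models, ModelSuite):
        models = models.models
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    members = gate_models(models, gate)
    if not members:
        scored = [m.evaluation.tss for m in models
                  if not m.failed and m.evaluation is not None]
        best = max(scored) if scored else float("nan")
        raise ValueError(f"no model reaches the TSS gate {gate}; best TSS = {best:.3f}")
    if method == "weighted":
        tss = np.array([m.evaluation.tss for m in members], dtype=float)
        weights = tss / tss.sum()
    else:
        weights = np.full(len(members), 1.0 / len(members))
    return Ensemble(method, members, weights, gate)


def project(ensemble: Ensemble, stack: RasterStack) -> np.ndarray:
    """Project an ensemble onto a stack: 0-1000 grid, NaN at nodata.

    The stack must provide every predictor the members were trained on.
    """
    needed = ensemble.members[0].feature_names
    missing = [n for n in needed if n not in stack.names]
    if missing:
        raise ValueError(f"stack is missing predictors: {missing}")
    out = np.full(stack.shape, np.nan)
    X, rows, cols = stack.table(needed)
    if len(X):
        Xdf = pd.DataFrame(X, columns=needed)
        out[rows, cols] = _round_half_up(1000.0 * ensemble.predict(Xdf))
    return out


def evaluate_ensemble(suite: ModelSuite, dataset: ModelingDataset, method: str,
                      gate: float = 0.8) -> EvaluationResult:
    """Pooled out-of-fold evaluation of an ensemble method.

    For each repetition, the gated members *of that repetition* are combined
    on that repetition's validation rows (so no member ever scores a row it
    trained on); predictions are pooled across repetitions and scored once.
    """
    obs_all, pred_all = [], []
    for rep in range(1, dataset.n_reps + 1):
        members = [m for m in gate_models(suite.models, gate) if m.repetition == rep]
        if not members:
            continue
        ens = Ensemble(method, members,
                       weights=_weights_for(members, method), gate=gate)
        val = ~dataset.splits[rep - 1]
        obs_all.append(dataset.y[val])
        pred_all.append(ens.predict(dataset.X[val]))
    if not obs_all:
        raise ValueError(f"no repetition has a member passing the TSS gate {gate}")
    return tss_optimize(np.concatenate(obs_all), np.concatenate(pred_all))


def _weights_for(members: list[FittedModel], method: str) -> np.ndarray:
    if method == "weighted":
        tss = np.array([m.evaluation.tss for m in members], dtype=float)
        return tss / tss.sum()
    return np.full(len(members), 1.0 / len(members))


def importance_table(suite: ModelSuite, X: pd.DataFrame, n_perm: int = 3,
                     seed: int = 0) -> pd.DataFrame:
    """Permutation importance per (variable, algorithm), plus the row mean.

    Rows are variables, columns the algorithms (averaged over repetitions)
    and a final ``Mean`` column averaging across algorithms — the layout of
    a standard variable-importance report.
    """
    algos = sorted({m.algorithm for m in suite.models},
                   key=lambda a: [m.algorithm for m in suite.models].index(a))
    table = pd.DataFrame(index=list(X.columns), columns=algos, dtype=float)
    for algo in algos:
        models = [m for m in suite.models if m.algorithm == algo]
        for var in X.columns:
            vals = [permutation_importance(
                        m.predict, X, var, n_perm=n_perm,
                        rng=subseed(seed, "importance", algo, m.repetition, var))
                    for m in models]
            table.loc[var, algo] = float(np.mean(vals))
    table["Mean"] = table[algos].mean(axis=1)
    return table
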