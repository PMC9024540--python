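"""Presence/absence model scoring: ROC-AUC, threshold-optimized TSS, and
permutation variable importance.

TSS (true skill statistic) = sensitivity + specificity - 1 at a cutoff; the
reported score is the maximum over all candidate cutoffs (midpoints between
sorted unique scores, plus 0 and 1), with the smallest maximizing cutoff kept
as the model's binarization threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class EvaluationResult:
    auc: float
    tss: float
    tss_threshold: float
    sensitivity: float
    specificity: float


def _check_labels(obs) -> np.ndarray:
    obs = np.asarray(obs)
    classes = np.unique(obs)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present to evaluate")
    return obs.astype(int)


def roc_auc(obs, scores) -> float:
    """Rank-based (Mann-Whitney) AUC; ties handled by midranks."""
    obs = _check_labels(obs)
    return float(roc_auc_score(obs, np.asarray(scores, dtype=float)))


def tss_curve(obs, scores):
    """Sensitivity, specificity and TSS at every candidate cutoff.

    Candidates are the midpoints between consecutive sorted unique scores,
    plus 0 and 1.  Returns (cutoffs, sensitivity, specificity).
    """
    obs = _check_labels(obs)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.empty(0)
    cutoffs = np.unique(np.concatenate([[0.0], mids, [1.0]]))
    pred = scores[None, :] >= cutoffs[:, None]
    pos, neg = obs == 1, obs == 0
    sens = (pred[:, pos]).mean(axis=1)
    spec = (~pred[:, neg]).mean(axis=1)
    return cutoffs, sens, spec


def tss_optimize(obs, scores) -> EvaluationResult:
    """Maximize TSS over candidate cutoffs; smallest maximizing cutoff wins."""
    cutoffs, sens, spec = tss_curve(obs, scores)
    tss = sens + spec - 1
    best = int(np.argmax(tss))  # argmax returns the first (smallest) cutoff
    return EvaluationResult(
        auc=roc_auc(obs, scores),
        tss=float(tss[best]),
        tss_threshold=float(cutoffs[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
    )


def permutation_importance(predict, X, variable: str, n_perm: int = 3,
                           rng: np.random.Generator | None = None) -> float:
    """Importance of one predictor as one minus correlation score.

    The variable's column is permuted (others fixed), the model re-predicts,
    and importance = mean over permutations of max(0, 1 - Pearson r(original,
    permuted predictions)).  0 means the model ignores the variable.
    """
    if variable not in X.columns:
        raise KeyError(f"variable '{variable}' not in data")
    rng = rng if rng is not None else np.random.default_rng(0)
    base = np.asarray(predict(X), dtype=float)
    if np.std(base) == 0:
        warnings.warn("constant predictions; importance defined as 0")
        return 0.0
    vals = []
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[variable] = rng.permutation(Xp[variable].to_numpy())
        perm = np.asarray(predict(Xp), dtype=float)
        if np.std(perm) == 0:
            r = 0.0 if not np.allclose(perm, base) else 1.0
        else:
            r = float(np.corrcoef(base, perm)[0, 1])
        vals.append(max(0.0, 1.0 - r))
    return float(np.mean(vals))
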