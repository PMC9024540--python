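"""Collinearity screening of predictor layers by pairwise Pearson correlation.

Bioclimatic predictors are strongly inter-correlated; the standard remedy in
distribution modeling is to compute the pairwise Pearson matrix over the
model-fitting extent and keep a subset whose pairwise |r| stays below a
threshold (0.75 here by default).  Which member of a correlated group is kept
is not determined by the matrix alone, so the selection takes an explicit
priority order (default: input order) — the reproducibility knob.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import RasterStack


@dataclass
class CorrelationReport:
    """Pairwise Pearson matrix plus the retained/dropped bookkeeping."""

    matrix: pd.DataFrame
    retained: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)  # dropped -> representative
    threshold: float | None = None

    def max_retained_abs_r(self) -> float:
        """Certificate value: max pairwise |r| among retained layers."""
        if len(self.retained) < 2:
            return 0.0
        sub = self.matrix.loc[self.retained, self.retained].to_numpy(dtype=float)
        off = np.abs(sub[~np.eye(len(sub), dtype=bool)])
        return float(np.nanmax(off))


def correlation_matrix(stack: RasterStack, points: np.ndarray | None = None,
                       names: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson r between layers over valid cells.

    By default all valid raster cells are used; pass ``points`` as an
    (n, 2) array of lon/lat to correlate at sample locations instead.
    Zero-variance layers get NaN rows/columns (apart from the unit diagonal)
    and a warning; downstream selection drops them.
    """
    names = list(names) if names is not None else list(stack.names)
    if points is not None:
        X = stack.values_at(np.asarray(points)[:, 0], np.asarray(points)[:, 1], names)
        X = X[np.isfinite(X).all(axis=1)]
    else:
        X, _, _ = stack.table(names)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 valid samples to correlate layers")
    sd = X.std(axis=0)
    constant = [n for n, s in zip(names, sd) if s == 0]
    if constant:
        warnings.warn(f"zero-variance layers, correlation undefined: {constant}")
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(X, rowvar=False)
    mat = np.asarray(mat, dtype=float)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=names, columns=names)


def select_uncorrelated(matrix: pd.DataFrame, threshold: float = 0.75,
                        priority: Sequence[str] | None = None) -> CorrelationReport:
    """Greedy threshold filter over a pairwise Pearson matrix.

    Layers are visited in ``priority`` order (layers not listed follow in
    input order); a layer is kept iff |r| <= threshold against every layer
    already kept.  Layers with undefined (NaN) correlations are dropped with
    a warning.  The retained set is certified: its max pairwise |r| is
    asserted to be <= threshold before returning.
    """
    names = list(matrix.index)
    if list(matrix.columns) != names:
        raise ValueError("correlation matrix must be square with matching labels")
    order = list(priority) if priority is not None else []
    unknown = [n for n in order if n not in names]
    if unknown:
        raise ValueError(f"priority names not in matrix: {unknown}")
    order += [n for n in names if n not in order]

    # pre-drop layers with no defined off-diagonal correlation at all
    # (zero-variance layers), unless the matrix is too small to tell which
    # side is degenerate — the greedy pass below then resolves it
    off = matrix.copy()
    np.fill_diagonal(off.values, np.nan)
    defined = off.notna().any(axis=1)
    predrop = set(off.index[~defined]) if defined.any() else set()

    retained: list[str] = []
    dropped: dict[str, str] = {}
    for name in order:
        if name in predrop:
            warnings.warn(f"layer '{name}' has undefined correlations; dropped")
            dropped[name] = ""
            continue
        conflict = None
        for kept in retained:
            r = matrix.loc[name, kept]
            if np.isnan(r) or abs(r) > threshold:
                conflict = kept
                break
        if conflict is None:
            retained.append(name)
        else:
            dropped[name] = conflict
            if np.isnan(matrix.loc[name, conflict]):
                warnings.warn(f"layer '{name}' has undefined correlations; dropped")

    report = CorrelationReport(matrix=matrix, retained=retained,
                               dropped=dropped, threshold=threshold)
    cert = report.max_retained_abs_r()
    assert cert <= threshold + 1e-12, f"retained-set certificate violated: {cert}"
    return report
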