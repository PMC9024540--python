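"""Bundled worked-example tables.

Small fixed inputs with known expected outputs, used in the documentation and
tests: a pairwise Pearson correlation matrix among the 19 WorldClim
bioclimatic variables over a Himalayan study region, per-algorithm
permutation-importance scores for the eight predictors retained there, and
range-change pixel counts for four future climate scenarios (RCP 4.5/8.5 at
2050/2070) under both ensemble methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_BIOCLIM_NAMES = [f"bio_{i}" for i in range(1, 20)]

# lower triangle, row k holds r(bio_k, bio_1..bio_{k-1})
_BIOCLIM_LOWER = """
0.63
0.52 0.56
-0.39 -0.05 -0.78
0.91 0.71 0.24 0
0.94 0.51 0.67 -0.63 0.75
-0.08 0.25 -0.63 0.91 0.31 -0.38
0.46 0.18 0.39 -0.4 0.32 0.53 -0.32
0.92 0.5 0.32 -0.27 0.88 0.84 0.01 0.23
0.92 0.67 0.25 -0.02 0.99 0.77 0.26 0.34 0.88
0.95 0.55 0.68 -0.63 0.76 0.99 -0.35 0.51 0.85 0.78
0.33 -0.26 0.42 -0.7 0 0.48 -0.7 0.41 0.24 0.06 0.48
0.18 -0.28 0.48 -0.74 -0.15 0.39 -0.78 0.38 0.06 -0.1 0.37 0.91
0.04 -0.08 -0.66 0.59 0.27 -0.14 0.59 -0.2 0.2 0.28 -0.14 -0.38 -0.65
0.06 -0.21 0.57 -0.77 -0.25 0.31 -0.81 0.35 -0.06 -0.23 0.29 0.72 0.91 -0.84
0.21 -0.26 0.5 -0.73 -0.12 0.41 -0.77 0.36 0.1 -0.06 0.4 0.93 0.99 -0.63 0.89
0.26 -0.23 -0.36 -0.01 0.27 0.19 0.1 -0.04 0.43 0.26 0.21 0.16 -0.13 0.66 -0.32 -0.12
0.29 -0.06 0.6 -0.68 -0.02 0.44 -0.68 0.48 0.12 0.03 0.45 0.9 0.88 -0.6 0.76 0.9 -0.2
0.32 -0.03 -0.32 0.07 0.38 0.19 0.25 -0.11 0.51 0.36 0.23 0.04 -0.29 0.68 -0.46 -0.26 0.94 -0.25
"""

#: Priority under which the greedy 0.75 filter reproduces the retained set
#: of the worked example.
BIOCLIM_EXAMPLE_PRIORITY = ["bio_1", "bio_2", "bio_3", "bio_7",
                            "bio_8", "bio_12", "bio_14", "bio_17"]


def bioclim_correlation_example() -> pd.DataFrame:
    """Symmetric 19 x 19 Pearson correlation matrix (unit diagonal)."""
    n = len(_BIOCLIM_NAMES)
    mat = np.eye(n)
    rows = [r.split() for r in _BIOCLIM_LOWER.strip().splitlines()]
    for k, vals in enumerate(rows, start=1):
        mat[k, :k] = [float(v) for v in vals]
        mat[:k, k] = mat[k, :k]
    return pd.DataFrame(mat, index=_BIOCLIM_NAMES, columns=_BIOCLIM_NAMES)


_IMPORTANCE = """
variable GLM GBM GAM CTA ANN SRE FDA RF MAXENT
bio_01 0.80 0.14 0.66 0.27 0.60 0.48 0.39 0.06 0.69
bio_02 0.59 0.02 0.70 0.00 0.43 0.34 0.02 0.03 0.27
bio_03 0.19 0.08 0.61 0.09 0.16 0.21 0.01 0.05 0.12
bio_07 0.37 0.08 0.65 0.07 0.20 0.19 0.06 0.04 0.29
bio_08 0.09 0.01 0.41 0.02 0.38 0.22 0.26 0.02 0.54
bio_12 0.49 0.02 0.65 0.08 0.59 0.34 0.08 0.02 0.49
bio_14 0.07 0.06 0.55 0.21 0.13 0.23 0.15 0.11 0.30
bio_17 0.54 0.13 0.82 0.64 0.78 0.36 0.25 0.06 0.57
"""


def importance_scores_example() -> pd.DataFrame:
    """Per-algorithm permutation-importance scores (rows = variables)."""
    lines = [ln.split() for ln in _IMPORTANCE.strip().splitlines()]
    df = pd.DataFrame(lines[1:], columns=lines[0]).set_index("variable")
    return df.astype(float)


_RANGE_COUNTS = """
scenario ensemble_type loss absent stable gain
RCP4.5-2050 committee 22334 895491 16690 6514
RCP4.5-2070 committee 34439 898663 4585 3342
RCP8.5-2050 committee 34801 898511 4223 3494
RCP8.5-2070 committee 38196 900519 828 1486
RCP4.5-2050 weighted 25408 885378 21537 8706
RCP4.5-2070 weighted 39793 889563 7152 4521
RCP8.5-2050 weighted 38494 889352 8451 4732
RCP8.5-2070 weighted 45560 891102 1385 2982
"""


def range_change_counts_example() -> pd.DataFrame:
    """Loss/absent/stable/gain pixel counts for eight scenario runs."""
    lines = [ln.split() for ln in _RANGE_COUNTS.strip().splitlines()]
    df = pd.DataFrame(lines[1:], columns=lines[0])
    for col in ("loss", "absent", "stable", "gain"):
        df[col] = df[col].astype(int)
    return df
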