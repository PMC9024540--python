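"""PCA-env niche quantification: occurrence-density grids in a 2-D principal
component space, Schoener's D overlap, and permutation tests.

The environmental space is the plane of the first two principal components of
the centered+scaled *pooled* background climates of the periods under
comparison, so both periods are projected with one set of loadings.  Each
entity's occupancy grid z is its kernel-smoothed occurrence density divided
by the background (availability) density on an R x R grid spanning the
pooled background extremes, then normalized to sum 1.  Overlap is
D = 1 - 1/2 * sum |z1 - z2| (0 = disjoint niches, 1 = identical).

Two permutation tests accompany D: the *equivalency* test pools and randomly
reassigns the two occurrence sets (are the niches interchangeable?), and the
*similarity* test relocates one niche uniformly at random within its
background envelope (is the observed overlap larger than chance placement
would give?).  p-values use the (count + 1) / (reps + 1) convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

_ENV_EPS = 1e-12


@dataclass
class PCAEnvModel:
    """Shared 2-D ordination of environmental space for two periods."""

    scaler: StandardScaler
    pca: PCA
    feature_names: list[str]

    @property
    def explained_pct(self) -> tuple[float, float]:
        v = self.pca.explained_variance_ratio_ * 100.0
        return float(v[0]), float(v[1])

    @property
    def loadings(self) -> np.ndarray:
        return self.pca.components_.T  # (n_features, 2)

    def transform(self, X) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(np.asarray(X, float)))


def fit_pca_env(env_current: np.ndarray, env_future: np.ndarray,
                feature_names: list[str] | None = None) -> PCAEnvModel:
    """PCA on the centered+scaled pooled background samples of both periods.

    Constant predictors are dropped with a warning before fitting.
    """
    cur = np.asarray(env_current, dtype=float)
    fut = np.asarray(env_future, dtype=float)
    if cur.ndim != 2 or fut.ndim != 2 or cur.shape[1] != fut.shape[1]:
        raise ValueError("current/future samples must be 2-D with equal columns")
    pooled = np.vstack([cur, fut])
    if pooled.shape[0] < 3 or pooled.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 predictors")
    names = list(feature_names) if feature_names is not None \
        else [f"x{i}" for i in range(pooled.shape[1])]
    keep = pooled.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"constant predictors dropped from PCA-env: {dropped}")
        pooled = pooled[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    if pooled.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant predictors")
    scaler = StandardScaler().fit(pooled)
    pca = PCA(n_components=2).fit(scaler.transform(pooled))
    model = PCAEnvModel(scaler, pca, names)
    # restrict transform to the kept columns
    kept_idx = np.nonzero(keep)[0]
    if not keep.all():
        orig_transform = model.transform

        def transform(X, _idx=kept_idx, _f=orig_transform):
            return _f(np.asarray(X, float)[:, _idx])

        model.transform = transform  # type: ignore[method-assign]
    return model


@dataclass
class NicheGrid:
    """R x R densities in PCA space: occurrence, background, occupancy z."""

    occ_density: np.ndarray
    env_density: np.ndarray
    z: np.ndarray
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    bandwidth: tuple[float, float] = (0.0, 0.0)

    @property
    def R(self) -> int:
        return self.z.shape[0]


def _silverman_bandwidth(values: np.ndarray, span: float) -> float:
    n = len(values)
    sd = float(np.std(values))
    if sd == 0 or n < 2:
        return max(1e-3 * span, 1e-9)
    return sd * n ** (-1.0 / 6.0)  # bivariate Silverman/Scott rule


def _axis_kernel(axis_centers: np.ndarray, values: np.ndarray,
                 bandwidth: float) -> np.ndarray:
    d = (axis_centers[:, None] - values[None, :]) / bandwidth
    return np.exp(-0.5 * d * d)


def _kde2d(points: np.ndarray, x_centers: np.ndarray, y_centers: np.ndarray,
           hx: float, hy: float) -> np.ndarray:
    """Product-Gaussian KDE evaluated on a grid, rows = y, cols = x."""
    gx = _axis_kernel(x_centers, points[:, 0], hx)  # (R, n)
    gy = _axis_kernel(y_centers, points[:, 1], hy)
    dens = gy @ gx.T  # (Ry, Rx)
    total = dens.sum()
    return dens / total if total > 0 else dens


def _grid_centers(rng: tuple[float, float], R: int) -> np.ndarray:
    lo, hi = rng
    if hi <= lo:
        hi = lo + 1e-9
    step = (hi - lo) / R
    return lo + (np.arange(R) + 0.5) * step


def density_grid(background_scores: np.ndarray, occurrence_scores: np.ndarray,
                 R: int = 100,
                 x_range: tuple[float, float] | None = None,
                 y_range: tuple[float, float] | None = None,
                 env_density: np.ndarray | None = None) -> NicheGrid:
    """Occupancy grid z on an R x R lattice bounded by background extremes.

    z is the occurrence kernel density divided by the background kernel
    density wherever the background has support, then normalized to sum 1.
    ``env_density`` may be passed in to reuse a background density across
    many calls (permutation tests).
    """
    bg = np.asarray(background_scores, dtype=float)
    occ = np.asarray(occurrence_scores, dtype=float)
    if occ.shape[0] < 5:
        raise ValueError("need at least 5 occurrences to build a density grid")
    x_range = x_range if x_range is not None else (bg[:, 0].min(), bg[:, 0].max())
    y_range = y_range if y_range is not None else (bg[:, 1].min(), bg[:, 1].max())
    inside = ((occ[:, 0] >= x_range[0]) & (occ[:, 0] <= x_range[1])
              & (occ[:, 1] >= y_range[0]) & (occ[:, 1] <= y_range[1]))
    if not inside.any():
        raise ValueError("all occurrences fall outside the background envelope")
    xc, yc = _grid_centers(x_range, R), _grid_centers(y_range, R)
    if env_density is None:
        hbx = _silverman_bandwidth(bg[:, 0], x_range[1] - x_range[0])
        hby = _silverman_bandwidth(bg[:, 1], y_range[1] - y_range[0])
        env_density = _kde2d(bg, xc, yc, hbx, hby)
    hox = _silverman_bandwidth(occ[:, 0], x_range[1] - x_range[0])
    hoy = _silverman_bandwidth(occ[:, 1], y_range[1] - y_range[0])
    occ_density = _kde2d(occ, xc, yc, hox, hoy)
    support = env_density > _ENV_EPS * env_density.max()
    z = np.zeros_like(occ_density)
    z[support] = occ_density[support] / env_density[support]
    total = z.sum()
    if total > 0:
        z /= total
    return NicheGrid(occ_density, env_density, z, tuple(x_range), tuple(y_range),
                     (hox, hoy))


def schoener_d(z1: np.ndarray, z2: np.ndarray) -> float:
    """Niche overlap D = 1 - 1/2 * sum |z1 - z2| on normalized grids."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("density grids must share a shape")
    out = []
    for z in (z1, z2):
        s = z.sum()
        if not np.isclose(s, 1.0):
            warnings.warn("density grid not normalized; normalizing internally")
            z = z / s if s > 0 else z
        out.append(z)
    return float(1.0 - 0.5 * np.abs(out[0] - out[1]).sum())


@dataclass
class OverlapTestResult:
    D: float
    null_distribution: np.ndarray
    p_value: float
    reps: int
    alternative: str
    extras: dict = field(default_factory=dict)


def _p_value(null: np.ndarray, observed: float, alternative: str) -> float:
    if alternative == "lower":
        count = int((null <= observed).sum())
    elif alternative == "greater":
        count = int((null >= observed).sum())
    else:
        raise ValueError("alternative must be 'lower' or 'greater'")
    return (count + 1) / (len(null) + 1)


def equivalency_test(occ1_scores: np.ndarray, occ2_scores: np.ndarray,
                     background_scores: np.ndarray, R: int = 100,
                     reps: int = 99, seed: int = 0,
                     alternative: str = "lower") -> OverlapTestResult:
    """Niche equivalency: pooled-reassignment null for Schoener's D.

    Under the null the two occurrence sets are interchangeable samples of one
    niche; each rep reassigns the pooled points to two groups of the original
    sizes and recomputes D.  With ``alternative='lower'``,
    p = (#{D_null <= D_obs} + 1) / (reps + 1): small p means the observed
    overlap is lower than reassignment can explain, rejecting equivalency.
    """
    if reps < 19:
        raise ValueError("reps must be >= 19")
    occ1 = np.asarray(occ1_scores, dtype=float)
    occ2 = np.asarray(occ2_scores, dtype=float)
    if len(occ1) < 5 or len(occ2) < 5:
        raise ValueError("need at least 5 occurrences per group")
    bg = np.asarray(background_scores, dtype=float)
    ranges = ((bg[:, 0].min(), bg[:, 0].max()), (bg[:, 1].min(), bg[:, 1].max()))
    base = density_grid(bg, occ1, R, *ranges)
    env = base.env_density  # reused across all grids: same background
    z2 = density_grid(bg, occ2, R, *ranges, env_density=env)
    d_obs = schoener_d(base.z, z2.z)

    pooled = np.vstack([occ1, occ2])
    n1 = len(occ1)
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for i in range(reps):
        perm = rng.permutation(len(pooled))
        g1, g2 = pooled[perm[:n1]], pooled[perm[n1:]]
        za = density_grid(bg, g1, R, *ranges, env_density=env)
        zb = density_grid(bg, g2, R, *ranges, env_density=env)
        null[i] = schoener_d(za.z, zb.z)
    return OverlapTestResult(d_obs, null, _p_value(null, d_obs, alternative),
                             reps, alternative)


def _wrap(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    return (values - lo) % span + lo


def similarity_test(z1: NicheGrid, occ2_scores: np.ndarray,
                    background2_scores: np.ndarray, reps: int = 99,
                    seed: int = 0,
                    alternative: str = "greater") -> OverlapTestResult:
    """Niche similarity: random-relocation null for Schoener's D.

    Each rep translates niche 2's occurrence cloud so its centroid lands at a
    uniformly random location inside niche 2's background envelope (mass
    wraps at the grid edges), rebuilds z2 and recomputes D against the fixed
    z1.  With ``alternative='greater'``,
    p = (#{D_null >= D_obs} + 1) / (reps + 1): small p means the niches are
    more similar than random placement in the background would give.
    """
    if reps < 19:
        raise ValueError("reps must be >= 19")
    occ2 = np.asarray(occ2_scores, dtype=float)
    if len(occ2) < 5:
        raise ValueError("need at least 5 occurrences")
    bg2 = np.asarray(background2_scores, dtype=float)
    x_range, y_range = z1.x_range, z1.y_range
    if x_range[1] - x_range[0] <= 0 or y_range[1] - y_range[0] <= 0:
        raise ValueError("degenerate background envelope; cannot shift")
    R = z1.R
    env2 = density_grid(bg2, occ2, R, x_range, y_range).env_density
    z2 = density_grid(bg2, occ2, R, x_range, y_range, env_density=env2)
    d_obs = schoener_d(z1.z, z2.z)

    lo = np.array([max(x_range[0], bg2[:, 0].min()), max(y_range[0], bg2[:, 1].min())])
    hi = np.array([min(x_range[1], bg2[:, 0].max()), min(y_range[1], bg2[:, 1].max())])
    centroid = occ2.mean(axis=0)
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for i in range(reps):
        target = lo + rng.random(2) * (hi - lo)
        shifted = occ2 + (target - centroid)
        shifted[:, 0] = _wrap(shifted[:, 0], x_range[0], x_range[1])
        shifted[:, 1] = _wrap(shifted[:, 1], y_range[0], y_range[1])
        zs = density_grid(bg2, shifted, R, x_range, y_range, env_density=env2)
        null[i] = schoener_d(z1.z, zs.z)
    return OverlapTestResult(d_obs, null, _p_value(null, d_obs, alternative),
                             reps, alternative)
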