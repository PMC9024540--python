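"""Virtual climates and virtual species with known ground truth.

The generator emulates the ingredients of a climate-based distribution
modeling study without any downloads: a stack of spatially autocorrelated,
cross-correlated "bioclimatic" layers on a lon/lat grid; a virtual species
whose true habitat suitability is a product of Gaussian responses to a known
subset of layers; presence samples drawn from that suitability; and future
scenarios produced by shifting/scaling layers so the direction of range
change is known a priori.

Spatial autocorrelation comes from Gaussian-smoothing white noise; the target
cross-correlation structure is then imposed exactly by empirically whitening
the smoothed fields and recoloring them with a matrix square root of the
target correlation matrix.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .occurrences import OccurrenceSet
from .raster import GridGeoreference, RasterStack


@dataclass(frozen=True)
class ClimateSpec:
    """Recipe for a synthetic climate stack.

    ``spatial_range`` is the autocorrelation length in cells (Gaussian sigma);
    ``cross_correlation`` the target layer-pair Pearson matrix (identity if
    omitted); ``nodata_fraction`` masks a random common fraction of cells.
    """

    n_layers: int
    grid_shape: tuple[int, int] = (100, 100)
    spatial_range: float = 4.0
    cross_correlation: np.ndarray | None = None
    nodata_fraction: float = 0.0
    seed: int = 0
    x_origin: float = 70.0
    y_origin: float = 37.0
    resolution: float = 0.05

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if min(self.grid_shape) < 10:
            raise ValueError("grid_shape dims must be >= 10")
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be > 0")
        if not 0 <= self.nodata_fraction < 1:
            raise ValueError("nodata_fraction must be in [0, 1)")

    def correlation_target(self) -> np.ndarray:
        if self.cross_correlation is None:
            return np.eye(self.n_layers)
        C = np.asarray(self.cross_correlation, dtype=float)
        if C.shape != (self.n_layers, self.n_layers):
            raise ValueError("cross_correlation must be n_layers x n_layers")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("cross_correlation must be symmetric with unit diagonal")
        return C


@dataclass(frozen=True)
class VirtualSpecies:
    """Ground-truth species: Gaussian response per driving layer."""

    response_means: tuple[float, ...]
    response_widths: tuple[float, ...]
    driving_layers: tuple[int, ...]
    prevalence_target: float = 0.1

    def __post_init__(self):
        if len(self.driving_layers) == 0:
            raise ValueError("driving_layers must be non-empty")
        if not (len(self.response_means) == len(self.response_widths)
                == len(self.driving_layers)):
            raise ValueError("means, widths and driving_layers lengths must match")
        if any(w <= 0 for w in self.response_widths):
            raise ValueError("response widths must be > 0")
        if not 0 < self.prevalence_target < 1:
            raise ValueError("prevalence_target must be in (0, 1)")


@dataclass(frozen=True)
class ScenarioShift:
    """Per-layer affine change: layer' = layer * factor + offset."""

    additive_deltas: tuple[float, ...]
    multiplicative_deltas: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.multiplicative_deltas is not None:
            if len(self.multiplicative_deltas) != len(self.additive_deltas):
                raise ValueError("delta vectors must have equal length")
            if any(f <= 0 for f in self.multiplicative_deltas):
                raise ValueError("multiplicative factors must be > 0")

    def factors(self) -> np.ndarray:
        if self.multiplicative_deltas is None:
            return np.ones(len(self.additive_deltas))
        return np.asarray(self.multiplicative_deltas, dtype=float)


def _matrix_sqrt(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    if vals.min() < -1e-8:
        raise ValueError(
            f"cross_correlation is not positive semi-definite "
            f"(min eigenvalue {vals.min():.3g})")
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0, None))) @ vecs.T


def generate_climate(spec: ClimateSpec) -> RasterStack:
    """Generate coregistered climate-like layers per the spec.

    Independent white-noise fields are smoothed (autocorrelation), empirically
    whitened across layers, recolored with the square root of the target
    correlation matrix and standardized, so the empirical cross-layer Pearson
    correlations match the target essentially exactly.  Identical specs give
    bit-identical stacks.
    """
    C = spec.correlation_target()
    rng = np.random.default_rng(spec.seed)
    nr, nc = spec.grid_shape
    fields = rng.standard_normal((spec.n_layers, nr, nc))
    for i in range(spec.n_layers):
        fields[i] = ndimage.gaussian_filter(fields[i], sigma=spec.spatial_range,
                                            mode="reflect")
    flat = fields.reshape(spec.n_layers, -1)
    flat -= flat.mean(axis=1, keepdims=True)
    # empirical whitening, then recoloring: imposes the target exactly
    cov = (flat @ flat.T) / flat.shape[1]
    flat = np.linalg.inv(np.linalg.cholesky(cov)) @ flat
    flat = _matrix_sqrt(C) @ flat
    flat /= flat.std(axis=1, keepdims=True)

    data = flat.reshape(spec.n_layers, nr, nc)
    if spec.nodata_fraction > 0:
        n_mask = int(round(spec.nodata_fraction * nr * nc))
        idx = rng.choice(nr * nc, size=n_mask, replace=False)
        flatview = data.reshape(spec.n_layers, -1)
        flatview[:, idx] = np.nan

    georef = GridGeoreference(spec.x_origin, spec.y_origin,
                              spec.resolution, -spec.resolution)
    names = [f"bio{i + 1:02d}" for i in range(spec.n_layers)]
    return RasterStack(names, data, georef)


def true_suitability(stack: RasterStack, sp: VirtualSpecies) -> np.ndarray:
    """Ground-truth suitability in [0, 1]: product of per-layer Gaussian
    responses over the driving layers, rescaled so the best valid cell is 1.

    Nodata propagates as NaN.
    """
    for i in sp.driving_layers:
        if not 0 <= i < stack.n_layers:
            raise ValueError(f"driving layer index {i} not in stack")
    if not stack.valid_mask.any():
        raise ValueError("stack has no valid cells")
    suit = np.ones(stack.shape)
    for i, mean, width in zip(sp.driving_layers, sp.response_means,
                              sp.response_widths):
        suit *= np.exp(-0.5 * ((stack.data[i] - mean) / width) ** 2)
    peak = np.nanmax(suit)
    if peak > 0:
        suit = suit / peak
    suit[~stack.valid_mask] = np.nan
    return suit


def sample_occurrences(suit: np.ndarray, stack: RasterStack, n: int,
                       seed: int = 0, species: str = "virtualis") -> OccurrenceSet:
    """Draw presence cells with probability proportional to suitability,
    without replacement (one presence per cell); coordinates at cell centers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    flat = np.where(np.isfinite(suit), suit, 0.0).ravel()
    eligible = int((flat > 0).sum())
    if n > eligible:
        raise ValueError(f"requested {n} presences but only {eligible} cells "
                         "have positive suitability")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    rows, cols = np.unravel_index(idx, suit.shape)
    lons, lats = stack.georef.cell_centers(rows, cols)
    return OccurrenceSet(lons, lats, species, ["synthetic"] * n)


def apply_scenario(stack: RasterStack, shift: ScenarioShift) -> RasterStack:
    """Future layer set: layer' = layer * factor + offset; mask unchanged."""
    offsets = np.asarray(shift.additive_deltas, dtype=float)
    factors = shift.factors()
    if len(offsets) != stack.n_layers:
        raise ValueError(f"shift has {len(offsets)} deltas for "
                         f"{stack.n_layers} layers")
    data = stack.data * factors[:, None, None] + offsets[:, None, None]
    return stack.with_layer_data(data)
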