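"""Configuration-driven orchestration of the full workflow.

The stages mirror a standard ensemble distribution-modeling study: thin
occurrences -> filter collinear predictors -> sample pseudo-absences -> fit
the nine-algorithm suite over repetitions -> build TSS-gated ensembles ->
project each scenario -> range-change statistics -> PCA-env niche dynamics.
One global seed fans out deterministically to per-stage sub-seeds, and every
paper-style default (0.75 correlation cutoff, 0.8 TSS gate, 80/20 splits x 3,
10,000 pseudo-absences, 100 x 100 niche grid) sits in :class:`RunConfig`.

For self-contained runs, :func:`simulate_study` builds a virtual-species
study (current climate, known suitability, presences, one contraction and
one expansion scenario) whose ground truth downstream stages can be checked
against.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._random import subseed
from .ensemble import build_ensemble, evaluate_ensemble, importance_table, project
from .models import build_dataset, fit_suite, make_splits, sample_pseudo_absences
from .niche import density_grid, equivalency_test, fit_pca_env, schoener_d, similarity_test
from .occurrences import OccurrenceSet, thin_occurrences
from .predictors import correlation_matrix, select_uncorrelated
from .rangechange import binarize, range_change_stats, stats_table
from .raster import RasterStack, read_stack, write_geotiff, write_stack
from .synthetic import (ClimateSpec, ScenarioShift, VirtualSpecies,
                        apply_scenario, generate_climate, sample_occurrences,
                        true_suitability)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a run; defaults follow the conventional study design."""

    outdir: str = "run"
    seed: int = 0
    occurrences: str | None = None        # CSV path; None -> synthetic
    layers_current: str | None = None     # stack dir; None -> synthetic
    scenarios: dict[str, str] = field(default_factory=dict)  # name -> stack dir
    correlation_threshold: float = 0.75
    priority: list[str] | None = None
    min_thin_dist_km: float = 0.0
    n_pseudo_absences: int = 10_000
    train_frac: float = 0.8
    reps: int = 3
    tss_gate: float = 0.8
    niche_grid_size: int = 100
    niche_reps: int = 99
    importance_perms: int = 3
    background_max: int = 10_000
    niche_entity_max: int = 1_000
    # synthetic-study knobs (used when no input paths are given)
    synthetic: dict = field(default_factory=dict)

    def validate(self) -> None:
        checks = [
            (0 < self.correlation_threshold <= 1, "correlation_threshold in (0,1]"),
            (0 <= self.tss_gate <= 1, "tss_gate in [0,1]"),
            (0 < self.train_frac < 1, "train_frac in (0,1)"),
            (self.reps >= 1, "reps >= 1"),
            (self.n_pseudo_absences >= 1, "n_pseudo_absences >= 1"),
            (self.niche_grid_size >= 5, "niche_grid_size >= 5"),
            (self.niche_reps >= 19, "niche_reps >= 19"),
            (self.min_thin_dist_km >= 0, "min_thin_dist_km >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: expected {msg}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticStudy:
    """A virtual-species study with known ground truth."""

    stack: RasterStack
    species: VirtualSpecies
    suitability: np.ndarray
    occurrences: OccurrenceSet
    scenarios: dict[str, RasterStack]
    shifts: dict[str, ScenarioShift]


def simulate_study(seed: int = 0, n_layers: int = 6,
                   grid_shape: tuple[int, int] = (120, 120),
                   n_presences: int = 250, nodata_fraction: float = 0.02,
                   correlated_pair_r: float = 0.85) -> SyntheticStudy:
    """Build a self-contained virtual study.

    The climate has one strongly correlated layer pair (|r| above the 0.75
    filter cutoff, to exercise predictor filtering) and otherwise nearly
    independent layers.  The species responds to layers 0 and 2, with layer 0
    dominant.  Two future scenarios come with known direction of change: a
    ``contraction`` shift pushes layer 0 far off the species optimum, and an
    ``expansion`` shift compresses layers toward the optimum so more cells
    become suitable.
    """
    C = np.eye(n_layers)
    C[-2, -1] = C[-1, -2] = correlated_pair_r
    spec = ClimateSpec(n_layers=n_layers, grid_shape=grid_shape,
                       spatial_range=4.0, cross_correlation=C,
                       nodata_fraction=nodata_fraction, seed=seed)
    stack = generate_climate(spec)
    species = VirtualSpecies(response_means=(0.8, -0.4),
                             response_widths=(0.25, 0.35),
                             driving_layers=(0, 2),
                             prevalence_target=0.05)
    suit = true_suitability(stack, species)
    occ = sample_occurrences(suit, stack, n_presences,
                             seed=int(subseed(seed, "occ").integers(2**31)))

    # cooling layer 0 means suitability now requires original values ~2.3 sd
    # into the field's upper tail, so the suitable area genuinely shrinks
    off_contraction = np.zeros(n_layers)
    off_contraction[0] = -1.5
    contraction = ScenarioShift(tuple(off_contraction))
    # pull driving layers toward the optimum: x' = mu + 0.5 (x - mu)
    off_expansion = np.zeros(n_layers)
    fac_expansion = np.ones(n_layers)
    for idx, mu in zip(species.driving_layers, species.response_means):
        fac_expansion[idx] = 0.5
        off_expansion[idx] = 0.5 * mu
    expansion = ScenarioShift(tuple(off_expansion), tuple(fac_expansion))
    shifts = {"contraction": contraction, "expansion": expansion}
    scenarios = {name: apply_scenario(stack, s) for name, s in shifts.items()}
    return SyntheticStudy(stack, species, suit, occ, scenarios, shifts)


def _background_sample(stack: RasterStack, names: list[str], max_n: int,
                       rng: np.random.Generator) -> np.ndarray:
    X, _, _ = stack.table(names)
    if len(X) > max_n:
        X = X[rng.choice(len(X), size=max_n, replace=False)]
    return X


def _suitable_cell_sample(stack: RasterStack, names: list[str],
                          binary_grid: np.ndarray, max_n: int,
                          rng: np.random.Generator) -> np.ndarray:
    rows, cols = np.nonzero(binary_grid == 1)
    if rows.size == 0:
        raise ValueError("no suitable cells to characterize the niche")
    if rows.size > max_n:
        pick = rng.choice(rows.size, size=max_n, replace=False)
        rows, cols = rows[pick], cols[pick]
    idx = [stack.names.index(n) for n in names]
    return stack.data[idx][:, rows, cols].T


def run_all(config: RunConfig) -> Path:
    """Execute every stage and write a self-describing run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- inputs -----------------------------------------------------------
    if config.layers_current is None or config.occurrences is None:
        study = simulate_study(seed=seed, **config.synthetic)
        stack, occ = study.stack, study.occurrences
        scenarios = study.scenarios
        write_stack(stack, outdir / "layers_current")
        occ.to_csv(outdir / "occurrences.csv")
    else:
        stack = read_stack(config.layers_current)
        occ = OccurrenceSet.from_csv(config.occurrences)
        scenarios = {name: read_stack(path)
                     for name, path in config.scenarios.items()}
    for name, sc in scenarios.items():
        if sc.names != stack.names:
            raise ValueError(f"scenario '{name}' does not provide the same layers")

    # --- thin + filter ----------------------------------------------------
    occ_thin = thin_occurrences(occ, stack, config.min_thin_dist_km)
    occ_thin.to_csv(outdir / "occurrences_thinned.csv")
    log.info("thinning: %d -> %d points", len(occ), len(occ_thin))

    corr = correlation_matrix(stack)
    report = select_uncorrelated(corr, config.correlation_threshold,
                                 config.priority)
    retained = report.retained
    corr.round(4).to_csv(outdir / "correlation_matrix.csv")
    (outdir / "retained_predictors.json").write_text(json.dumps({
        "retained": retained, "dropped": report.dropped,
        "threshold": config.correlation_threshold,
        "max_retained_abs_r": report.max_retained_abs_r()}, indent=2))
    log.info("predictor filter: %d -> %d layers", stack.n_layers, len(retained))

    # --- dataset + suite --------------------------------------------------
    pa = sample_pseudo_absences(stack, occ_thin, config.n_pseudo_absences,
                                seed=int(subseed(seed, "pa").integers(2**31)))
    dataset = build_dataset(stack, occ_thin, pa, retained)
    make_splits(dataset, config.train_frac, config.reps,
                seed=int(subseed(seed, "splits").integers(2**31)))
    suite = fit_suite(dataset, seed=seed)
    suite.scores().round(6).to_csv(outdir / "model_scores.csv", index=False)
    for m in suite.failures:
        log.warning("model failed: %s rep %d (%s)", m.algorithm, m.repetition,
                    m.failure_reason)

    # --- ensembles, evaluation, importance --------------------------------
    ens_rows, ensembles, thresholds = [], {}, {}
    for method in ("committee", "weighted"):
        ens = build_ensemble(suite, method, config.tss_gate)
        ev = evaluate_ensemble(suite, dataset, method, config.tss_gate)
        ensembles[method] = ens
        thresholds[method] = ev.tss_threshold * 1000.0
        ens_rows.append({"method": method, "n_members": len(ens.members),
                         "auc": ev.auc, "tss": ev.tss,
                         "tss_threshold": ev.tss_threshold,
                         "sensitivity": ev.sensitivity,
                         "specificity": ev.specificity})
    pd.DataFrame(ens_rows).round(6).to_csv(outdir / "ensemble_evaluation.csv",
                                           index=False)
    imp = importance_table(suite, dataset.X, config.importance_perms,
                           seed=int(subseed(seed, "imp").integers(2**31)))
    imp.round(4).to_csv(outdir / "importance.csv")

    # --- projection + range change ---------------------------------------
    all_stacks = {"current": stack, **scenarios}
    projections: dict[tuple[str, str], np.ndarray] = {}
    for sc_name, sc_stack in all_stacks.items():
        for method, ens in ensembles.items():
            grid = project(ens, sc_stack)
            projections[(sc_name, method)] = grid
            write_geotiff(outdir / f"suitability_{sc_name}_{method}.tif",
                          grid, stack.georef, stack.crs, dtype=np.int32)
    rc_rows = []
    for method in ensembles:
        cur_bin = binarize(projections[("current", method)],
                           thresholds[method], "current")
        for sc_name in scenarios:
            fut_bin = binarize(projections[(sc_name, method)],
                               thresholds[method], sc_name)
            stats, change = range_change_stats(cur_bin, fut_bin)
            rc_rows.append((sc_name, method, stats))
            write_geotiff(outdir / f"change_{sc_name}_{method}.tif", change,
                          stack.georef, stack.crs, dtype=np.int16)
    stats_table(rc_rows).to_csv(outdir / "range_change.csv", index=False)

    # --- niche dynamics ---------------------------------------------------
    niche_rows = []
    rng = subseed(seed, "niche")
    for sc_name, sc_stack in scenarios.items():
        bg_cur = _background_sample(stack, retained, config.background_max, rng)
        bg_fut = _background_sample(sc_stack, retained, config.background_max, rng)
        pca = fit_pca_env(bg_cur, bg_fut, retained)
        ent_cur = _suitable_cell_sample(
            stack, retained,
            binarize(projections[("current", "weighted")],
                     thresholds["weighted"]).grid,
            config.niche_entity_max, rng)
        ent_fut = _suitable_cell_sample(
            sc_stack, retained,
            binarize(projections[(sc_name, "weighted")],
                     thresholds["weighted"]).grid,
            config.niche_entity_max, rng)
        s_bg = np.vstack([pca.transform(bg_cur), pca.transform(bg_fut)])
        s_cur, s_fut = pca.transform(ent_cur), pca.transform(ent_fut)
        ranges = ((s_bg[:, 0].min(), s_bg[:, 0].max()),
                  (s_bg[:, 1].min(), s_bg[:, 1].max()))
        R = config.niche_grid_size
        z_cur = density_grid(s_bg, s_cur, R, *ranges)
        z_fut = density_grid(s_bg, s_fut, R, *ranges,
                             env_density=z_cur.env_density)
        d = schoener_d(z_cur.z, z_fut.z)
        eq = equivalency_test(s_cur, s_fut, s_bg, R=R, reps=config.niche_reps,
                              seed=int(subseed(seed, "eq", sc_name).integers(2**31)))
        sim = similarity_test(z_cur, s_fut, s_bg, reps=config.niche_reps,
                              seed=int(subseed(seed, "sim", sc_name).integers(2**31)))
        pc1, pc2 = pca.explained_pct
        niche_rows.append({"Pair": f"current vs {sc_name}",
                           "PC1(%)": round(pc1, 2), "PC2(%)": round(pc2, 2),
                           "Overlap(D)": round(d, 4),
                           "Equivalency p": round(eq.p_value, 5),
                           "Similarity p": round(sim.p_value, 5)})
    pd.DataFrame(niche_rows).to_csv(outdir / "niche.csv", index=False)

    manifest = {"package_version": __version__, "seed": seed,
                "config": config.to_dict(),
                "n_models": len(suite.models),
                "n_failures": len(suite.failures)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
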