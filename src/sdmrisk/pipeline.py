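"""Single-config orchestration of the full analysis.

Stages, in order, for each species (pest and host): thin presences → screen
correlated predictors (once, on the current-climate stack) → kernel-density
bias surface and weighted background sample → candidate feature-set × RM
grid under shared CV folds → three-key ranking → refit of the best candidate
on all presences → projection to the current and each future slice → MTSPS
threshold from pooled held-out fold predictions → four-class maps. Then the
pest and host maps are overlaid per slice and per-class areas and percent
changes are written.

Every stage is an importable library function; this module only wires them
together, resolves defaults, and records a reproducibility log (seeds,
thresholds, retained variables, ranked candidates) sufficient to re-execute
the run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import evaluation as ev
from .grids import GridStack, read_grid, align_stack, write_grid
from .maxent import FeatureConfig, fit_from_values, predict, predict_scores
from .occurrences import (OccurrenceSet, bias_surface, load_occurrences,
                          sample_background, thin)
from .predictors import correlation_matrix, default_priority, select_variables
from .synthetic import (TruthParams, make_climate, make_future, sample_presences,
                        true_suitability)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class SyntheticSpec:
    """Inputs generated on the fly instead of read from disk."""

    shape: tuple[int, int] = (40, 40)
    n_vars: int = 4
    pest: TruthParams = field(default_factory=TruthParams)
    host: TruthParams = field(default_factory=lambda: TruthParams(
        temp_optimum=20.1, temp_sd=4.3))
    future_slices: dict[str, dict] = field(default_factory=lambda: {
        "2050": {"delta_temp": 1.5, "precip_scale": 0.95},
        "2070": {"delta_temp": 2.0, "precip_scale": 0.90},
    })


@dataclass
class RunConfig:
    """Declarative description of one full run; defaults are study-faithful."""

    outdir: str = "run"
    seed: int = 0
    thin_km: float = 10.0
    thin_reps: int = 10
    corr_cutoff: float = 0.75
    background_n: int = 50_000
    bias_bandwidth_km: float = 200.0
    feature_sets: list[str] = field(default_factory=lambda: list(ev.PAPER_FEATURE_SETS))
    rms: list[float] = field(default_factory=lambda: list(ev.PAPER_RMS))
    folds_k: int = 10
    clamp: str = "fade"
    geodesic: bool = True
    n_hinge_knots: int = 20
    n_threshold_knots: int = 20
    # file-based inputs: per-species occurrence CSVs and per-slice raster lists
    occurrences: dict[str, str] = field(default_factory=dict)   # role -> csv path
    species_labels: dict[str, str] = field(default_factory=dict)  # role -> csv label
    rasters: dict[str, list[str]] = field(default_factory=dict)  # slice -> paths
    synthetic: SyntheticSpec | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            pest = TruthParams(**syn.pop("pest", {}))
            host = syn.pop("host", {})
            host.setdefault("temp_optimum", 20.1)
            host.setdefault("temp_sd", 4.3)
            shape = tuple(syn.pop("shape", (40, 40)))
            cfg.synthetic = SyntheticSpec(shape=shape, pest=pest,
                                          host=TruthParams(**host), **syn)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def quickstart_config(outdir: str, seed: int = 0) -> RunConfig:
    """The synthetic quick-start preset: small enough to run in seconds."""
    return RunConfig(
        outdir=outdir,
        seed=seed,
        background_n=2_000,
        bias_bandwidth_km=1_500.0,  # broad relative to the ~3500 km window
        feature_sets=["LQ", "LQP", "LQH"],
        rms=[1.0],
        folds_k=3,
        n_hinge_knots=10,
        n_threshold_knots=10,
        synthetic=SyntheticSpec(
            shape=(32, 32),
            pest=TruthParams(n_presence=200, seed=1),
            host=TruthParams(temp_optimum=20.1, temp_sd=4.3, n_presence=200, seed=2),
            future_slices={"2050": {"delta_temp": 1.5, "precip_scale": 0.95}},
        ),
    )


def _load_stacks(config: RunConfig) -> dict[str, GridStack]:
    if config.synthetic is not None:
        syn = config.synthetic
        current = make_climate(shape=syn.shape, n_vars=syn.n_vars,
                               seed=config.seed + 1000)
        stacks = {"current": current}
        for label, kw in syn.future_slices.items():
            stacks[label] = make_future(current, slice_label=label, **kw)
        return stacks
    stacks = {}
    for label, paths in config.rasters.items():
        grids = []
        for p in paths:
            if not os.path.exists(p):
                raise StageError(f"load_rasters: missing raster path {p!r}")
            grids.append(read_grid(p))
        stacks[label] = align_stack(grids, slice_label=label)
    if "current" not in stacks:
        raise StageError("load_rasters: a 'current' slice is required")
    return stacks


def _load_occurrences(config: RunConfig, stacks: dict[str, GridStack],
                      outdir: str) -> dict[str, OccurrenceSet]:
    if config.synthetic is not None:
        out = {}
        for role, params in (("pest", config.synthetic.pest),
                             ("host", config.synthetic.host)):
            truth = true_suitability(stacks["current"], params)
            occ = sample_presences(truth, None, params.n_presence,
                                   seed=params.seed + config.seed, species=role)
            out[role] = occ
        return out
    out = {}
    for role, path in config.occurrences.items():
        if not os.path.exists(path):
            raise StageError(f"load_occurrences: missing CSV {path!r}")
        label = config.species_labels.get(role, role)
        out[role] = load_occurrences(path, label)
    if not {"pest", "host"} <= set(out):
        raise StageError("load_occurrences: roles 'pest' and 'host' are required")
    return out


def run_all(config: RunConfig) -> str:
    """Execute every stage and write all artifacts; returns the run directory."""
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    run_log: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        return run_log["stages"].setdefault(name, {})

    try:
        stacks = _load_stacks(config)
        current = stacks["current"]
        occs = _load_occurrences(config, stacks, outdir)

        # --- thinning
        info = stage("thin")
        thinned = {}
        for role, occ in occs.items():
            t = thin(occ, min_dist_km=config.thin_km, reps=config.thin_reps,
                     seed=config.seed + 10)
            thinned[role] = t
            t.to_csv(os.path.join(outdir, f"occurrences_{role}_thinned.csv"))
            info[role] = {"before": len(occ), "after": len(t)}

        # --- predictor screening (once, on the current stack)
        info = stage("select_variables")
        corr = correlation_matrix(current)
        corr.to_frame().to_csv(os.path.join(outdir, "correlation_matrix.csv"))
        priority = default_priority(corr.variables)
        retained = select_variables(corr, priority, cutoff=config.corr_cutoff)
        info["retained"] = retained
        info["priority"] = priority
        info["cutoff"] = config.corr_cutoff

        results: dict[str, dict] = {}
        for role in ("pest", "host"):
            occ = thinned[role]
            info = stage(f"model_{role}")
            bias = bias_surface(occ, current.template,
                                bandwidth_km=config.bias_bandwidth_km)
            bg = sample_background(current, bias, n=config.background_n,
                                   seed=config.seed + 20)
            values_bg = {v: current[v].values[tuple(bg.cells.T)] for v in retained}
            vp_all = current.values_at_points(occ.points)
            values_pres = {v: vp_all[v] for v in retained}

            folds = ev.make_folds(len(occ), k=config.folds_k, seed=config.seed + 30)
            records = ev.run_candidate_grid(
                config.feature_sets, config.rms, values_pres, values_bg, folds,
                seed=config.seed + 40, n_hinge_knots=config.n_hinge_knots,
                n_threshold_knots=config.n_threshold_knots)
            table = ev.records_to_frame(records)
            table.to_csv(os.path.join(outdir, f"model_selection_{role}.csv"),
                         index=False)
            best = ev.rank_models(records)[0]
            info["best"] = {"features": best.features, "rm": best.rm,
                            "auc_cv": best.auc_cv_mean, "or0": best.or0,
                            "or10": best.or10}

            best_cfg = FeatureConfig(classes=best.features, rm=best.rm,
                                     n_hinge_knots=config.n_hinge_knots,
                                     n_threshold_knots=config.n_threshold_knots)
            model = fit_from_values(values_pres, values_bg, best_cfg,
                                    seed=config.seed + 50)
            with open(os.path.join(outdir, f"model_{role}.lambdas.txt"), "w") as fh:
                fh.write(model.to_lambdas_text())

            # pooled held-out presence scores for the MTSPS threshold
            holdout = []
            for fold in range(1, folds.k + 1):
                tr, te = folds.train_test(fold)
                vp_tr = {v: values_pres[v][tr] for v in retained}
                vp_te = {v: values_pres[v][te] for v in retained}
                fm = fit_from_values(vp_tr, values_bg, best_cfg,
                                     seed=config.seed + 50)
                holdout.append(predict_scores(fm, vp_te))
            holdout = np.concatenate(holdout)
            bg_scores = predict_scores(model, values_bg)
            t = cls.mtsps_threshold(holdout, bg_scores)
            info["mtsps_threshold"] = t

            suits, classes = {}, {}
            for label, stack in stacks.items():
                s = predict(model, stack, clamp=config.clamp)
                suits[label] = s
                classes[label] = cls.classify_suitability(s, t)
                write_grid(s.grid, os.path.join(outdir, f"suitability_{role}_{label}.asc"))
                write_grid(classes[label].grid,
                           os.path.join(outdir, f"class_{role}_{label}.asc"))
            results[role] = {"model": model, "threshold": t, "classes": classes}

        # --- overlay per slice + areas
        info = stage("overlay")
        summaries = {}
        for label in stacks:
            host_mask = cls.optimal_mask(results["host"]["classes"][label])
            risk = cls.risk_overlay(results["pest"]["classes"][label], host_mask,
                                    pest_slice=label, host_slice=label)
            write_grid(risk.grid, os.path.join(outdir, f"risk_{label}.asc"))
            summaries[label] = cls.area_summary(risk, geodesic=config.geodesic)
        area_rows = []
        for label, df in summaries.items():
            d = df.copy()
            d.insert(0, "slice", label)
            area_rows.append(d)
        area_table = pd.concat(area_rows, ignore_index=True)
        area_table.to_csv(os.path.join(outdir, "area_summary.csv"), index=False)

        change_rows = []
        for label in stacks:
            if label == "current":
                continue
            ch = cls.change_stats(summaries["current"], summaries[label])
            ch.insert(0, "future_slice", label)
            change_rows.append(ch)
        if change_rows:
            pd.concat(change_rows, ignore_index=True).to_csv(
                os.path.join(outdir, "change_stats.csv"), index=False)
        info["slices"] = list(stacks)
    except StageError:
        raise
    except Exception as exc:  # tag unexpected failures with their stage context
        raise StageError(f"pipeline failed: {exc}") from exc

    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True, default=str)
    return outdir
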