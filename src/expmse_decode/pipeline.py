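"""End-to-end driver: simulate -> decompose -> entropy -> features ->
train -> evaluate -> saliency, with per-stage caching.

Each stage writes into per-subject HDF5 containers under the run
directory and records the hash of the configuration slice it depends
on; a rerun with an unchanged configuration skips the cached stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import io_h5
from .config import RunConfig
from .decoder import (cross_validate, make_inter_folds, make_intra_folds,
                      permute_trial_labels, spec_for_kind)
from .decompose import band_power_series, decompose_recording
from .entropy import EntropyParams, expmse_map
from .errors import ConfigError
from .features import (TWO_CLASS_MAP, build_crop_set, downsample_raw,
                       merge_crop_sets, segment_trials)
from .saliency import task_sensitivity_map
from .simulate import generate_cohort

log = logging.getLogger("expmse_decode")


def _subject_path(out_dir: Path, s: int) -> Path:
    return out_dir / "subjects" / f"subject{s:02d}.h5"


def _stage_done(path: Path, stage: str, stage_hash: str) -> bool:
    if not path.exists():
        return False
    with h5py.File(path, "r") as f:
        return f.attrs.get(f"stage_{stage}") == stage_hash


def _mark_stage(path: Path, stage: str, stage_hash: str) -> None:
    with h5py.File(path, "a") as f:
        f.attrs[f"stage_{stage}"] = stage_hash


def stage_simulate(config: RunConfig, out_dir: Path) -> list[Path]:
    sim = config.simulation.to_simulation_config(config.seed)
    effects = config.simulation.to_effects(sim)
    h = config.config_hash("simulation")
    paths = [_subject_path(out_dir, s) for s in range(sim.n_subjects)]
    if all(_stage_done(p, "simulate", h) for p in paths):
        log.info("[simulate] cached (%s)", h)
        return paths
    log.info("[simulate] %d subjects, %d regions, %d samples",
             sim.n_subjects, sim.n_regions, sim.n_samples)
    cohort = generate_cohort(sim, effects)
    for s, (rec, events) in enumerate(cohort):
        io_h5.write_subject(paths[s], rec, events)
        _mark_stage(paths[s], "simulate", h)
    return paths


def stage_decompose(config: RunConfig, out_dir: Path,
                    paths: list[Path]) -> None:
    h = config.config_hash("simulation", "decomposition")
    dec = config.decomposition
    for p in paths:
        if _stage_done(p, "decompose", h):
            log.info("[decompose] %s cached", p.name)
            continue
        rec, _ = io_h5.read_subject(p)
        log.info("[decompose] %s: EEMD x %d regions, %d ensembles",
                 p.name, rec.n_regions, dec.n_ensembles)
        comps = decompose_recording(
            rec, noise_sd_ratio=dec.noise_sd_ratio,
            n_ensembles=dec.n_ensembles, seed=config.seed,
            max_imf=dec.max_imf)
        io_h5.write_bands(p, comps)
        _mark_stage(p, "decompose", h)


def stage_entropy(config: RunConfig, out_dir: Path,
                  paths: list[Path]) -> None:
    h = config.config_hash("simulation", "decomposition", "entropy")
    ent = config.entropy
    params = EntropyParams(m=ent.m, r=ent.r)
    for p in paths:
        if _stage_done(p, "entropy", h):
            log.info("[entropy] %s cached", p.name)
            continue
        comps = io_h5.read_bands(p)
        log.info("[entropy] %s: expMSE map (cap %d)", p.name, ent.cap)
        tensor = expmse_map(comps, params=params, cap=ent.cap,
                            bin_s=ent.bin_s)
        io_h5.write_expmse(p, tensor)
        _mark_stage(p, "entropy", h)


def stage_features(config: RunConfig, out_dir: Path,
                   paths: list[Path]) -> None:
    h = config.config_hash("simulation", "decomposition", "entropy",
                           "features")
    feat = config.features
    for s, p in enumerate(paths):
        if _stage_done(p, "features", h):
            log.info("[features] %s cached", p.name)
            continue
        rec, events = io_h5.read_subject(p)
        windows = segment_trials(events, fs=rec.fs, subject=s,
                                 tasks=tuple(feat.decoded_tasks),
                                 bin_s=config.entropy.bin_s)
        log.info("[features] %s: %d trial windows", p.name, len(windows))
        for kind in feat.kinds:
            if kind == "expmse":
                source = io_h5.read_expmse(p)
            elif kind == "bandpower":
                comps = io_h5.read_bands(p)
                source = band_power_series(comps, bin_s=config.entropy.bin_s)
            elif kind == "raw":
                source = downsample_raw(rec, target=200.0)
            else:
                raise ConfigError(f"unknown feature kind {kind!r}")
            crop_set = build_crop_set(
                source, windows, kind, k=feat.crop_k,
                raw_win=feat.raw_window, raw_step=feat.raw_step)
            io_h5.write_crops(p, crop_set)
        _mark_stage(p, "features", h)


def stage_decode(config: RunConfig, out_dir: Path, paths: list[Path],
                 keep_models: bool = False) -> dict:
    """Train and evaluate; returns the aggregated report dict."""
    dec = config.decoder
    kind = dec.kind
    crop_sets = [io_h5.read_crops(p, kind) for p in paths]
    for s, cs in enumerate(crop_sets):
        cs.trial_meta["subject"] = s
    if dec.two_class:
        crop_sets = [cs.relabel(TWO_CLASS_MAP) for cs in crop_sets]
    results = {"design": dec.design, "kind": kind, "folds": [],
               "subjects": []}
    all_models, all_plans, all_sets = [], [], []
    if dec.design == "intra":
        for s, cs in enumerate(crop_sets):
            if dec.permute_labels:
                cs = permute_trial_labels(cs, config.seed + 977 + s)
            plan = make_intra_folds(cs.trial_meta, seed=config.seed + s)
            spec = _spec(config, cs)
            out = cross_validate(cs, plan, spec, keep_models=keep_models)
            report, models = out if keep_models else (out, [])
            log.info("[decode] subject %d: %.1f +/- %.1f %%",
                     s, report.mean, report.sd)
            results["subjects"].append(
                {"subject": s, "mean": report.mean, "sd": report.sd,
                 "fold_accuracy": report.fold_accuracy,
                 "n_decisions": report.n_decisions,
                 "overall": report.overall_accuracy})
            all_models.append(models)
            all_plans.append(plan)
            all_sets.append(cs)
    elif dec.design == "inter":
        merged = merge_crop_sets(crop_sets)
        if dec.permute_labels:
            merged = permute_trial_labels(merged, config.seed + 977)
        plan = make_inter_folds(merged.trial_meta, seed=config.seed)
        spec = _spec(config, merged)
        out = cross_validate(merged, plan, spec, keep_models=keep_models)
        report, models = out if keep_models else (out, [])
        results["subjects"].append(
            {"subject": "all", "mean": report.mean, "sd": report.sd,
             "fold_accuracy": report.fold_accuracy,
             "n_decisions": report.n_decisions,
             "overall": report.overall_accuracy})
        all_models.append(models)
        all_plans.append(plan)
        all_sets.append(merged)
    else:
        raise ConfigError(f"unknown design {dec.design!r}")
    means = [s["mean"] for s in results["subjects"]]
    results["mean"] = float(np.mean(means))
    results["sd"] = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    results["n_decisions"] = int(sum(s["n_decisions"]
                                     for s in results["subjects"]))
    correct = sum(s["overall"] * s["n_decisions"] / 100.0
                  for s in results["subjects"])
    results["overall"] = float(100.0 * correct / results["n_decisions"])
    report_path = out_dir / f"report_{dec.design}_{kind}.json"
    report_path.write_text(json.dumps(
        {k: v for k, v in results.items() if k != "_artifacts"}, indent=2))
    results["_artifacts"] = (all_models, all_plans, all_sets)
    return results


def _spec(config: RunConfig, crop_set):
    dec = config.decoder
    n_classes = len(set(crop_set.labels))
    input_shape = crop_set.data.shape[1:]
    return spec_for_kind(
        crop_set.kind, input_shape, n_classes,
        filters=tuple(dec.filters), learning_rate=dec.learning_rate,
        batch_size=dec.batch_size, patience=dec.patience,
        max_epochs=dec.max_epochs, seed=config.seed)


def stage_saliency(config: RunConfig, out_dir: Path,
                   results: dict) -> dict[str, pd.DataFrame]:
    """Per-task mean sensitivity maps from the decode artifacts."""
    models, plans, sets = results["_artifacts"]
    if not models or not models[0]:
        raise ConfigError("saliency needs decode run with keep_models")
    maps: dict[str, list[np.ndarray]] = {}
    for subj_models, plan, cs in zip(models, plans, sets):
        for task in sorted(set(cs.labels)):
            m = task_sensitivity_map(subj_models, cs, plan, task)
            maps.setdefault(task, []).append(m)
    out = {}
    columns = None
    if sets and sets[0].kind == "expmse":
        from .entropy import feature_columns
        columns = feature_columns()
    for task, ms in maps.items():
        mean_map = np.mean(ms, axis=0)
        df = pd.DataFrame(mean_map)
        if columns is not None and len(columns) == mean_map.shape[1]:
            df.columns = list(columns)
        df.to_csv(out_dir / f"saliency_{task}.csv", index=False)
        out[task] = df
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 with_saliency: bool = True) -> dict:
    """Run every stage; cached stages are skipped on reruns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text("")
    config.to_yaml(out_dir / "config.yaml")
    paths = stage_simulate(config, out_dir)
    stage_decompose(config, out_dir, paths)
    stage_entropy(config, out_dir, paths)
    stage_features(config, out_dir, paths)
    results = stage_decode(config, out_dir, paths,
                           keep_models=with_saliency)
    if with_saliency:
        stage_saliency(config, out_dir, results)
    results.pop("_artifacts", None)
    return results


__all__ = [
    "stage_simulate", "stage_decompose", "stage_entropy",
    "stage_features", "stage_decode", "stage_saliency", "run_pipeline",
]
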