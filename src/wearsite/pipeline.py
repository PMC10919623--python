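"""Stage functions chaining the library into a reproducible pipeline.

Each stage reads and writes documented CSV/JSON artifacts in a run
directory, so stages can be re-run independently (the CLI wraps these
functions one-to-one).  Every artifact embeds the run's config hash; window
and bout counts are logged at stage boundaries so the sample-feature
bookkeeping is always visible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import counts as counts_mod
from . import evaluation, groundtruth, io, models, synthdata, windowing
from .config import PipelineConfig, config_hash, config_to_dict

log = logging.getLogger("wearsite")


def _require(path: Path, stage: str, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"{stage}: missing input {path} — run `{hint}` first")
    return path


def _seed_for(config: PipelineConfig, stage: str, extra: str = "") -> int:
    h = int.from_bytes(f"{stage}:{extra}".encode()[:4].ljust(4, b"\0"), "big")
    return int(np.random.SeedSequence([config.seed, h]).generate_state(1)[0]
               % (2 ** 31))


def simulate(config: PipelineConfig, out_dir) -> dict:
    """Generate cohort, protocols, recordings and calorimetry on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    (out / "run_config.json").write_text(
        json.dumps({"config_hash": chash,
                    "config": config_to_dict(config)}, indent=2) + "\n")
    profiles = synthdata.sample_participants(
        config.cohort.n_adult, config.cohort.n_child,
        seed=_seed_for(config, "participants"))
    io.write_profiles(profiles, out / "profiles.csv", chash)
    data_dir = out / "data"
    entries = []
    for p in profiles:
        protocol = synthdata.draw_protocol(
            p, seed=_seed_for(config, "protocol", p.id),
            config=config.protocol)
        session = synthdata.simulate_session(
            p, protocol, config.cohort.sites,
            seed=_seed_for(config, "session", p.id),
            signal_config=config.signal,
            calorimetry_config=config.calorimetry)
        cal_file = f"data/{p.id}_calorimetry.csv"
        io.write_calorimetry(session.calorimetry, out / cal_file, chash)
        site_files = {}
        for site, rec in session.recordings.items():
            f = f"data/{p.id}_{site}.csv"
            io.write_recording(rec, out / f, chash)
            site_files[site] = f
        entries.append({
            "id": p.id, "group": p.group, "calorimetry": cal_file,
            "recordings": site_files,
            "rest": {"start_s": session.calorimetry.rest_start,
                     "end_s": session.calorimetry.rest_end},
            "bouts": [{
                "index": lat.bout_index,
                "start_s": lat.start_s, "end_s": lat.end_s,
                "activity": bout.activity.name,
                "category": bout.activity.category,
                "locomotor": bout.activity.locomotor,
                "met_draw": lat.met_draw,
                "reached_steady": lat.reached_steady,
            } for lat, bout in zip(session.latents, protocol.bouts)],
        })
    manifest = {"config_hash": chash, "seed": config.seed,
                "sites": list(config.cohort.sites),
                "sample_rate": config.signal.sample_rate,
                "participants": entries}
    io.write_manifest(manifest, out / "manifest.json")
    log.info("simulate: %d participants x %d sites written to %s",
             len(profiles), len(config.cohort.sites), out)
    return manifest


def run_groundtruth(config: PipelineConfig, out_dir) -> pd.DataFrame:
    """Resting VO2, steady-state VO2, METs and intensity per bout."""
    out = Path(out_dir)
    manifest = io.read_manifest(_require(out / "manifest.json", "groundtruth",
                                         "wearsite simulate"))
    rows = []
    for entry in manifest["participants"]:
        series = io.read_calorimetry(out / entry["calorimetry"],
                                     rest_start=entry["rest"]["start_s"],
                                     rest_end=entry["rest"]["end_s"])
        rest = groundtruth.resting_vo2(series, config.groundtruth)
        for b in entry["bouts"]:
            res = groundtruth.bout_result(series, b["index"], b["start_s"],
                                          b["end_s"], rest, config.groundtruth)
            rows.append({"participant_id": entry["id"], "group": entry["group"],
                         "bout_index": b["index"], "resting_vo2": rest,
                         "steady_vo2": res.steady_vo2, "mets": res.mets,
                         "intensity": res.intensity,
                         "exclusion_reason": res.exclusion_reason})
    df = pd.DataFrame(rows)
    io._write_csv(df, out / "bout_results.csv", manifest["config_hash"],
                  float_format="%.4f")
    n_excl = int(df["intensity"].isna().sum())
    log.info("groundtruth: %d bouts scored, %d excluded", len(df), n_excl)
    return df


def _bout_results_for(df: pd.DataFrame, pid: str) -> list:
    sub = df[df.participant_id == pid]
    return [groundtruth.BoutResult(
        bout_index=int(r.bout_index),
        steady_vo2=None if pd.isna(r.steady_vo2) else float(r.steady_vo2),
        mets=None if pd.isna(r.mets) else float(r.mets),
        intensity=None if pd.isna(r.intensity) else str(r.intensity),
        exclusion_reason=None if pd.isna(r.exclusion_reason)
        else str(r.exclusion_reason)) for r in sub.itertuples()]


def run_baseline(config: PipelineConfig, out_dir,
                 trim_s: float | None = None) -> dict:
    """Counts + hip cut-points applied at every recorded wear-site."""
    out = Path(out_dir)
    manifest = io.read_manifest(_require(out / "manifest.json", "baseline",
                                         "wearsite simulate"))
    bt = _require(out / "bout_results.csv", "baseline", "wearsite groundtruth")
    results = pd.read_csv(bt, comment="#")
    trim = config.windowing.trim_s if trim_s is None else trim_s
    epoch_s = counts_mod.ADULT_HIP_CUTPOINTS.epoch_s
    by_site: dict[str, list] = {s: [] for s in manifest["sites"]}
    for entry in manifest["participants"]:
        spans = [(b["start_s"], b["end_s"]) for b in entry["bouts"]]
        bres = _bout_results_for(results, entry["id"])
        cuts = counts_mod.DEFAULT_CUTPOINTS[entry["group"]]
        for site, f in entry["recordings"].items():
            rec = io.read_recording(out / f, site=site,
                                    sample_rate=manifest["sample_rate"])
            cs = counts_mod.raw_to_counts(rec, epoch_s=epoch_s,
                                          config=config.counts)
            pred = counts_mod.cutpoint_classify(cs, cuts)
            truth = counts_mod.epoch_truth_labels(cs, bres, spans, trim_s=trim)
            by_site[site].append({"group": entry["group"], "truth": truth,
                                  "pred": pred})
    summary = {"config_hash": manifest["config_hash"], "accuracy": {}}
    for site, per_part in by_site.items():
        report = counts_mod.misspecification_report(per_part, applied_site=site)
        io._write_csv(report, out / f"misspecification_{site}.csv",
                      manifest["config_hash"], float_format="%.2f")
        (out / f"misspecification_{site}.txt").write_text(
            evaluation.render_misspecification_table(report) + "\n")
        summary["accuracy"][site] = counts_mod.baseline_accuracy(report)
        log.info("baseline %s: overall correct %.1f%%", site,
                 summary["accuracy"][site])
    (out / "baseline_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    return summary


def build_windows(config: PipelineConfig, out_dir) -> windowing.LabeledWindowSet:
    """Segment every recording into labeled windows; cache as .npz."""
    out = Path(out_dir)
    manifest = io.read_manifest(_require(out / "manifest.json", "windows",
                                         "wearsite simulate"))
    bt = _require(out / "bout_results.csv", "windows", "wearsite groundtruth")
    results = pd.read_csv(bt, comment="#")
    profiles = {p.id: p for p in io.read_profiles(out / "profiles.csv")}
    w = config.windowing
    sets = []
    for entry in manifest["participants"]:
        bres = _bout_results_for(results, entry["id"])
        annotations = [(b["index"], b["start_s"], b["end_s"])
                       for b in entry["bouts"]]
        for site, f in entry["recordings"].items():
            rec = io.read_recording(out / f, site=site,
                                    sample_rate=manifest["sample_rate"],
                                    bout_annotations=annotations)
            sets.append(windowing.segment(rec, bres, profiles[entry["id"]],
                                          window_len=w.window_len,
                                          stride=w.stride, trim_s=w.trim_s))
    ws = windowing.LabeledWindowSet.concatenate(sets)
    if 0 < w.max_windows < len(ws):
        rng = np.random.default_rng(_seed_for(config, "window_cap"))
        keep = np.sort(rng.choice(len(ws), w.max_windows, replace=False))
        log.info("windows: subsampling %d of %d windows", w.max_windows,
                 len(ws))
        ws = ws.subset(keep)
    np.savez_compressed(out / "windows.npz", windows=ws.windows,
                        site=ws.site.astype(str),
                        intensity=ws.intensity.astype(str),
                        participant_id=ws.participant_id.astype(str),
                        group=ws.group.astype(str))
    log.info("windows: %d labeled windows cached", len(ws))
    return ws


def load_windows(out_dir) -> windowing.LabeledWindowSet:
    out = Path(out_dir)
    z = np.load(_require(out / "windows.npz", "train", "wearsite windows"))
    return windowing.LabeledWindowSet(
        windows=z["windows"], site=z["site"].astype(object),
        intensity=z["intensity"].astype(object),
        participant_id=z["participant_id"].astype(object),
        group=z["group"].astype(object))


def train_model(config: PipelineConfig, out_dir, task: str | None = None,
                architecture: str | None = None,
                use_covariates: bool | None = None) -> models.TrainedModel:
    """Train one configured classifier on the cached windows."""
    from dataclasses import replace
    out = Path(out_dir)
    ws = load_windows(out)
    cfg = config.model
    if task is not None:
        cfg = replace(cfg, task=task)
    if architecture is not None:
        cfg = replace(cfg, architecture=architecture)
    if use_covariates is not None:
        cfg = replace(cfg, use_covariates=use_covariates)
    cfg = replace(cfg, seed=_seed_for(config, "train", cfg.task))
    sites = models.TASK_CLASSES[cfg.task] if cfg.task.startswith("site") \
        else models.SITE_SCOPES["two_site"]
    keep = np.where(np.isin(ws.site, sites))[0]
    ws = ws.subset(keep)
    tr, va = windowing.split(ws, config.windowing.train_fraction,
                             seed=_seed_for(config, "split", cfg.task),
                             scheme=config.windowing.split_scheme)
    if cfg.use_covariates:
        profiles = io.read_profiles(out / "profiles.csv")
        tr = windowing.attach_covariates(tr, profiles, standardize=True)
        va = windowing.attach_covariates(va, profiles, standardize=True,
                                         stats=tr.covariate_stats)
    model = models.train(models.build_model(cfg), tr, va, cfg)
    name = f"{cfg.architecture}_{cfg.task}" + ("_cov" if cfg.use_covariates
                                               else "")
    (out / f"train_{name}.json").write_text(json.dumps({
        "config_hash": config_hash(config), "task": cfg.task,
        "architecture": cfg.architecture, "use_covariates": cfg.use_covariates,
        "n_train": len(tr), "n_val": len(va),
        "history": model.history,
        "final_val_accuracy": model.final_val_accuracy}, indent=2) + "\n")
    log.info("train %s: final validation accuracy %.3f", name,
             model.final_val_accuracy)
    return model


def evaluate_grid(config: PipelineConfig, out_dir, **grid_kwargs) -> pd.DataFrame:
    """Run the experiment grid on cached windows and render the tables."""
    out = Path(out_dir)
    ws = load_windows(out)
    profiles = io.read_profiles(out / "profiles.csv")
    grid = models.run_experiment_grid(
        ws, profiles, seed=_seed_for(config, "grid"),
        base_config=config.model,
        train_fraction=config.windowing.train_fraction,
        split_scheme=config.windowing.split_scheme, **grid_kwargs)
    io._write_csv(grid, out / "model_grid.csv", config_hash(config),
                  float_format="%.4f")
    (out / "model_grid.txt").write_text(
        evaluation.render_grid_table(grid) + "\n")
    return grid
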