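"""End-to-end orchestration: simulate -> preprocess -> ERP -> P3 latency ->
trial matching -> mixed-effects statistics, with reproducible file outputs.

Every random draw flows from a single global seed through named per-stage
substreams (:func:`stage_seed`), so a run is bit-reproducible. A run directory
contains one TSV per tabular artifact, the grand-average ERPs in the epoch
container format, a Table-1-style bin descriptives file per condition and sort
key, and ``manifest.json`` echoing the configuration and listing every
artifact with its SHA1 hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp as erp_mod
from . import matching as match_mod
from . import preprocess as pre_mod
from . import stats as stats_mod
from . import synthetic_data as synth
from . import woody as woody_mod
from .containers import SimulationConfig

__all__ = ["default_config", "stage_seed", "simulate_condition",
           "pooled_bin_descriptives", "run_pipeline", "report"]

_STAGE_IDS = {"stimuli": 1, "behavior_speeded": 2, "behavior_delayed": 3,
              "eeg": 4, "matching": 5}


def stage_seed(global_seed, stage, index=0):
    """Deterministic per-stage substream seed derived from the global seed."""
    sid = _STAGE_IDS.get(stage)
    if sid is None:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence((int(global_seed), sid, int(index)))
    return int(ss.generate_state(1)[0] % (2**31))


def default_config(**overrides):
    """Default run configuration (smoke scale: 2 subjects x 200 pairs)."""
    cfg = {
        "seed": 0,
        "n_subjects": 2,
        "n_pairs": 200,
        "conditions": ["speeded", "delayed"],
        "keep_channels": None,          # None = keep the full montage
        "simulation": {},               # SimulationConfig field overrides
        "preprocess": {"wide_band": [0.1, 50.0], "narrow_band": [0.5, 15.0],
                       "order": 3, "target_hz": 256,
                       "tmin": -0.1, "tmax": 1.5, "baseline": [-0.1, 0.0]},
        "erp": {"n_bins": 8},
        "woody": {},                    # WoodyConfig field overrides
        "matching": {"as_low_max": 1, "as_high_min": 18,
                     "p3_short_max": 0.5, "p3_long_min": 0.6,
                     "n_per_subject": 75,
                     "rt_target": 0.65, "p3_target": 0.65},
        "contrast": {"channel": "Pz", "window": [0.4, 0.5]},
    }
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _stimulus_blocks(n_pairs):
    # scale the 800/100/100 composition proportionally
    block = max(1, round(n_pairs / 8))
    return block, block


def simulate_condition(cfg, condition, trial_id_start=0):
    """Simulate and preprocess one condition, one subject at a time.

    Returns ``(epochs, trials, ground_truth)`` where ``epochs`` is the
    combined stimulus-locked EpochSet over all subjects (restricted to
    ``cfg['keep_channels']`` if set, to bound memory at full scale).
    """
    seed = cfg["seed"]
    pairs = synth.generate_stimulus_list(
        cfg["n_pairs"], *_stimulus_blocks(cfg["n_pairs"]),
        seed=stage_seed(seed, "stimuli"))
    profiles = synth.default_profiles(cfg["n_subjects"], condition, seed=seed)
    trials = synth.simulate_behavior(
        pairs, profiles, condition,
        seed=stage_seed(seed, f"behavior_{condition}"),
        trial_id_start=trial_id_start)

    pp = cfg["preprocess"]
    per_subject, gts = [], []
    for prof in profiles:
        sub_trials = trials[trials["subject_id"] == prof.subject_id]
        sim = SimulationConfig(n_subjects=1, n_pairs=cfg["n_pairs"],
                               condition=condition, **cfg["simulation"])
        rec, gt = synth.simulate_eeg(
            sub_trials, sim,
            seed=stage_seed(seed, "eeg",
                            index=prof.subject_id * 2
                            + (condition == "delayed")))
        ep = pre_mod.run_chain(
            rec, trials, wide_band=tuple(pp["wide_band"]),
            narrow_band=tuple(pp["narrow_band"]), order=pp["order"],
            target_hz=pp["target_hz"], tmin=pp["tmin"], tmax=pp["tmax"],
            baseline=tuple(pp["baseline"]))
        if cfg.get("keep_channels"):
            ep = pre_mod.select_channels(ep, cfg["keep_channels"])
        per_subject.append(ep)
        gts.append(gt)
        del rec
    epochs = pre_mod.concatenate_epochs(per_subject)
    return epochs, trials, pd.concat(gts, ignore_index=True)


def pooled_bin_descriptives(trials, assignments):
    """Table-1-style descriptives pooling per-subject bins across subjects."""
    frames = [a.assignment for a in assignments]
    pooled = pd.concat(frames, ignore_index=True).merge(trials, on="trial_id")
    rows = []
    for b, grp in pooled.groupby("bin"):
        resp = grp["response"].dropna()
        rows.append({
            "bin": b, "n": len(grp),
            "mean_as": grp["as_score"].mean(),
            "sd_as": grp["as_score"].std(ddof=1),
            "mean_rt": grp["rt_s"].mean(),
            "sd_rt": grp["rt_s"].std(ddof=1),
            "response_ratio": resp.mean() if len(resp) else np.nan,
        })
    return pd.DataFrame(rows)


def _subject_bins_and_erps(epochs, key, n_bins):
    assignments, erps = [], []
    for _, meta in epochs.metadata.groupby("subject_id", sort=True):
        sub = epochs.copy_with(
            data=epochs.data[meta.index.to_numpy()],
            metadata=meta.reset_index(drop=True))
        assignment = erp_mod.bin_trials(sub.metadata, key=key, n_bins=n_bins)
        assignments.append(assignment)
        erps.append(erp_mod.average_erp(sub, assignment))
    return assignments, erp_mod.grand_average(erps)


def _estimate_latencies_by_subject(speeded, delayed, woody_cfg):
    """Per-subject Woody estimation (speeded) and template re-use (delayed)."""
    tables = []
    for subject, meta in speeded.metadata.groupby("subject_id", sort=True):
        sub = speeded.copy_with(data=speeded.data[meta.index.to_numpy()],
                                metadata=meta.reset_index(drop=True))
        lt = woody_mod.estimate_latencies(
            sub, sub.metadata["rt_s"].to_numpy(), woody_cfg)
        lt.table["subject_id"] = subject
        lt.table["condition"] = "speeded"
        tables.append(lt)
        if delayed is not None:
            dmeta = delayed.metadata[delayed.metadata["subject_id"] == subject]
            if len(dmeta):
                dsub = delayed.copy_with(
                    data=delayed.data[dmeta.index.to_numpy()],
                    metadata=dmeta.reset_index(drop=True))
                dlt = woody_mod.reuse_template(lt.template, dsub, woody_cfg,
                                               template_sfreq=lt.sfreq)
                dlt.table["subject_id"] = subject
                dlt.table["condition"] = "delayed"
                tables.append(dlt)
    return tables


def _write_tsv(path, frame):
    frame.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(config=None, out=None, **overrides):
    """Run all stages and write artifacts under ``out``; returns the run dir."""
    cfg = default_config(**{**(config or {}), **overrides})
    outdir = Path(out or f"runs/run-seed{cfg['seed']}")
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    artifacts = {}

    def emit(name, frame):
        artifacts[name] = str(_write_tsv(outdir / name, frame))

    # --- simulate + preprocess -------------------------------------------
    pairs = synth.generate_stimulus_list(
        cfg["n_pairs"], *_stimulus_blocks(cfg["n_pairs"]),
        seed=stage_seed(cfg["seed"], "stimuli"))
    emit("stimuli.tsv", synth.stimulus_list_frame(pairs))

    epochs, trials, gts = {}, {}, {}
    offset = 0
    for condition in cfg["conditions"]:
        ep, tr, gt = simulate_condition(cfg, condition, trial_id_start=offset)
        offset += len(tr)
        epochs[condition], trials[condition], gts[condition] = ep, tr, gt
        emit(f"trials_{condition}.tsv", tr)
        emit(f"ground_truth_{condition}.tsv", gt)

    # --- ERPs and Table-1 analogue ---------------------------------------
    n_bins = cfg["erp"]["n_bins"]
    for condition in cfg["conditions"]:
        keys = ("as", "rt") if condition == "speeded" else ("as",)
        for key in keys:
            assignments, grand = _subject_bins_and_erps(
                epochs[condition], key, n_bins)
            emit(f"bins_{condition}_{key}.tsv",
                 pooled_bin_descriptives(trials[condition], assignments))
            np.savez(outdir / f"grand_erp_{condition}_{key}.npz",
                     waveforms=grand.waveforms, t0=grand.t0,
                     sfreq=grand.sfreq, n_trials=grand.n_trials)

    # --- single-trial P3 latencies ---------------------------------------
    results = {}
    if "speeded" in epochs:
        woody_cfg = woody_mod.WoodyConfig(**cfg["woody"])
        tables = _estimate_latencies_by_subject(
            epochs["speeded"], epochs.get("delayed"), woody_cfg)
        lat = pd.concat([t.table for t in tables], ignore_index=True)
        emit("latencies.tsv", lat)

        sp_lat = lat[lat["condition"] == "speeded"]
        sp = trials["speeded"].merge(
            sp_lat[["trial_id", "latency_s"]].rename(
                columns={"latency_s": "p3_latency_s"}), on="trial_id")
        lme_lat = stats_mod.fit_lme(
            sp, stats_mod.LmeSpec("p3_latency_s", "rt_s"))
        results["p3_latency_vs_rt"] = lme_lat

        # --- trial groups and contrasts ----------------------------------
        m = cfg["matching"]
        targets = match_mod.ScoringTargets(m["rt_target"], m["p3_target"])
        contrast = cfg["contrast"]
        try:
            fixed = match_mod.build_fixed_latency_groups(
                sp, as_low_max=m["as_low_max"], as_high_min=m["as_high_min"],
                n_per_subject=m["n_per_subject"], targets=targets)
            emit("groups_fixed_latency.tsv", fixed)
            results["fixed_latency_contrast"] = match_mod.contrast_groups(
                epochs["speeded"], fixed, group_a="lowAS", group_b="highAS",
                channel=contrast["channel"], window=tuple(contrast["window"]))
        except ValueError as err:
            results["fixed_latency_contrast"] = {"error": str(err)}
        if "delayed" in epochs:
            try:
                comp = match_mod.build_competition_groups(
                    sp, trials["delayed"].dropna(subset=["rt_s"]),
                    as_low_max=m["as_low_max"], as_high_min=m["as_high_min"],
                    p3_short_max=m["p3_short_max"],
                    p3_long_min=m["p3_long_min"],
                    seed=stage_seed(cfg["seed"], "matching"))
                emit("groups_competition.tsv", comp)
                results["competition_speeded"] = match_mod.contrast_groups(
                    epochs["speeded"], comp, group_a=1, group_b=2,
                    channel=contrast["channel"],
                    window=tuple(contrast["window"]))
                results["competition_delayed"] = match_mod.contrast_groups(
                    epochs["delayed"], comp, group_a=3, group_b=4,
                    channel=contrast["channel"],
                    window=tuple(contrast["window"]))
            except ValueError as err:
                results["competition_speeded"] = {"error": str(err)}

    # --- behavioural statistics ------------------------------------------
    lme_rows = []
    for condition in cfg["conditions"]:
        tr = trials[condition]
        log_fit = stats_mod.fit_lme(tr, stats_mod.LmeSpec("rt_s", "log_as"))
        raw_fit = stats_mod.fit_lme(
            tr[tr["as_score"] > 0], stats_mod.LmeSpec("rt_s", "as_score"))
        preferred, diff = stats_mod.compare_models(log_fit, raw_fit)
        for name, fit in (("rt~log_as", log_fit), ("rt~as", raw_fit)):
            lme_rows.append({"condition": condition, "model": name,
                             "w": fit.w, "se": fit.se, "t": fit.t, "p": fit.p,
                             "loglik": fit.loglik, "n": fit.n,
                             "n_excluded": fit.n_excluded})
        results[f"rt_model_preferred_{condition}"] = (
            preferred.spec.fixed, diff)
    for key, res in results.items():
        if isinstance(res, dict) and "lme" in res:
            lme = res["lme"]
            lme_rows.append({"condition": key, "model": "group_contrast",
                             "w": lme.w, "se": lme.se, "t": lme.t, "p": lme.p,
                             "loglik": lme.loglik, "n": lme.n,
                             "n_excluded": lme.n_excluded})
    emit("lme_results.tsv", pd.DataFrame(lme_rows))

    contrast_rows = []
    for key in ("competition_speeded", "competition_delayed",
                "fixed_latency_contrast"):
        res = results.get(key)
        if isinstance(res, dict) and "difference" in res:
            contrast_rows.append({
                "contrast": key, "mean_a": res["mean_a"],
                "mean_b": res["mean_b"], "difference": res["difference"],
                "n_a": res["n_per_group"][0], "n_b": res["n_per_group"][1],
                "t": res["lme"].t, "p": res["lme"].p})
        elif isinstance(res, dict) and "error" in res:
            contrast_rows.append({"contrast": key, "error": res["error"]})
    if contrast_rows:
        emit("contrasts.tsv", pd.DataFrame(contrast_rows))

    manifest = {
        "config": cfg,
        "elapsed_s": round(time.time() - t_start, 2),
        "artifacts": {
            name: {"path": path,
                   "sha1": hashlib.sha1(Path(path).read_bytes()).hexdigest()}
            for name, path in artifacts.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def report(run_dir):
    """Summarise a finished run: Table-1 analogues plus contrast signs.

    Regenerating the report from the same run directory is pure (byte-identical
    output). Missing stage outputs are listed under ``missing`` and the report
    is otherwise produced.
    """
    run_dir = Path(run_dir)
    out = {"tables": {}, "flags": {}, "missing": []}
    for name in sorted(run_dir.glob("bins_*.tsv")):
        tab = pd.read_csv(name, sep="\t")
        key = name.stem
        out["tables"][key] = tab
        rt = tab["mean_rt"].to_numpy()
        rr = tab["response_ratio"].to_numpy()
        out["flags"][key] = {
            "rt_monotone_increasing": bool(np.all(np.diff(rt) >= -1e-9)),
            "response_ratio_monotone_decreasing": bool(
                np.all(np.diff(rr) <= 1e-9)),
            "rt_range": [float(rt.min()), float(rt.max())],
        }
    contrasts = run_dir / "contrasts.tsv"
    if contrasts.exists():
        tab = pd.read_csv(contrasts, sep="\t")
        out["tables"]["contrasts"] = tab
        if "difference" in tab.columns:
            out["flags"]["contrast_signs"] = {
                row["contrast"]: ("positive" if row["difference"] > 0
                                  else "negative")
                for _, row in tab.iterrows() if pd.notna(row.get("difference"))
            }
    else:
        out["missing"].append("contrasts.tsv")
    for required in ("lme_results.tsv", "latencies.tsv", "stimuli.tsv"):
        if not (run_dir / required).exists():
            out["missing"].append(required)
    report_path = run_dir / "report.json"
    serializable = {
        "flags": out["flags"], "missing": out["missing"],
        "tables": {k: v.to_dict(orient="list") for k, v in out["tables"].items()},
    }
    report_path.write_text(json.dumps(serializable, indent=1, sort_keys=True))
    return out
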