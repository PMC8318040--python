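"""Configuration, orchestration, and reproducible end-to-end runs.

A run is described by one structured config document (YAML/dict) with a
block per stage. ``run_pipeline`` executes the requested stages in order
(simulate/load -> preprocess -> gfp -> cluster -> backfit -> features ->
stats -> classify), writes every artifact as TSV/JSON, and records a
manifest with the config echo, seeds, and content digests of all outputs,
so any artifact can be regenerated from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backfit as bf
from . import classify as cl
from . import cluster as cs
from . import features as ft
from . import gfp as gf
from . import io as eio
from . import stats as st
from . import synth as sg

__all__ = ["load_config", "validate_config", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger(__name__)

ALL_STAGES = ("preprocess", "gfp", "cluster", "backfit", "features", "stats", "classify")

DEFAULTS: dict = {
    "paths": {"out": "mstates_out"},
    "simulate": None,
    "preprocess": {"avg_ref": True, "band": None, "resample": None, "baseline": None},
    "gfp": {"smooth_window": 50},
    "cluster": {"th_gev": 0.85, "th_gmd": 0.1, "polarity": "invariant"},
    "backfit": {"min_duration": 3, "max_passes": 10},
    "features": {"window_s": None, "feature_set": "combined", "transition_level": "segment"},
    "stats": {"dimensions": ["valence", "arousal"], "alpha": 0.05, "fdr": False},
    "classify": {"classifier": "svm", "folds": 5, "seed": 17, "dimension": "valence"},
}


def load_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    return doc


def _merged(profile: dict) -> dict:
    out = {}
    for block, defaults in DEFAULTS.items():
        user = profile.get(block)
        if defaults is None:
            out[block] = user
        else:
            out[block] = {**defaults, **(user or {})}
    return out


def validate_config(profile: dict) -> list[str]:
    """Check every block against its stage's invariants; name offending keys."""
    findings: list[str] = []
    cfg = _merged(profile)
    if cfg["simulate"] is None and "input" not in cfg["paths"]:
        findings.append("paths.input: either an input path or a simulate block is required")
    if cfg["simulate"] is not None:
        try:
            sg.SynthConfig(**{k: v for k, v in cfg["simulate"].items()
                              if k not in ("n_trials_per_class", "low", "dimension")})
        except (TypeError, ValueError) as e:
            findings.append(f"simulate: {e}")
    try:
        cs.ClusteringConfig(
            th_gev=cfg["cluster"]["th_gev"],
            th_gmd=cfg["cluster"]["th_gmd"],
            polarity=cfg["cluster"]["polarity"],
        )
    except ValueError as e:
        findings.append(f"cluster.{e}" if "th_" in str(e) else f"cluster: {e}")
    try:
        bf.SmoothingConfig(
            min_duration=cfg["backfit"]["min_duration"],
            max_passes=cfg["backfit"]["max_passes"],
        )
    except ValueError as e:
        findings.append(f"backfit: {e}")
    if cfg["gfp"]["smooth_window"] < 1:
        findings.append("gfp.smooth_window: must be >= 1")
    band = cfg["preprocess"]["band"]
    if band is not None and not (0 < band[0] < band[1]):
        findings.append("preprocess.band: must satisfy 0 < low < high")
    if cfg["features"]["feature_set"] not in ("temporal", "transitions", "combined"):
        findings.append("features.feature_set: unknown value")
    if cfg["classify"]["classifier"] not in cl.CLASSIFIERS:
        findings.append("classify.classifier: unknown value")
    if not 0 < cfg["stats"]["alpha"] < 1:
        findings.append("stats.alpha: must lie in (0, 1)")
    return findings


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_trials(cfg: dict) -> tuple[eio.TrialSet, np.ndarray | None]:
    if cfg["simulate"] is not None:
        sim = dict(cfg["simulate"])
        n = sim.pop("n_trials_per_class", 10)
        low_over = sim.pop("low", {})
        dim = sim.pop("dimension", "valence")
        high = sg.SynthConfig(**sim)
        low = replace(high, **low_over) if low_over else high
        trials, templates = sg.make_dataset(high, low, n, seed=high.seed, dimension=dim)
        return trials, templates
    root = Path(cfg["paths"]["input"])
    ratings = eio.RatingTable(pd.read_csv(root / "ratings.tsv", sep="\t"))
    trials = []
    for _, row in ratings.table.iterrows():
        rec = eio.read_matrix(root / f"{row['trial_id']}.tsv", rate=cfg["paths"]["rate"])
        rec.meta["trial_id"] = row["trial_id"]
        trials.append(rec)
    return eio.TrialSet(trials=trials, ratings=ratings), None


def run_pipeline(profile: dict, stages=None) -> dict:
    """Execute the requested stages in order and return the run manifest."""
    findings = validate_config(profile)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    cfg = _merged(profile)
    stages = list(stages or ALL_STAGES)
    out = Path(cfg["paths"]["out"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"toolkit": "mstates 0.1.0", "config": cfg_serializable(cfg),
                      "stages": [], "warnings": []}

    def record(name: str, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": name,
                "outputs": {str(p): _digest(p) for p in outputs},
                "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )

    trials, _ = _load_trials(cfg)
    if cfg["simulate"] is not None:
        trials.ratings.table.to_csv(out / "ratings.tsv", sep="\t", index=False)
        record("simulate", [out / "ratings.tsv"])

    if "preprocess" in stages:
        pp = cfg["preprocess"]
        processed = []
        for rec in trials.trials:
            if pp["band"]:
                rec = eio.bandpass_filter(rec, *pp["band"])
            if pp["resample"]:
                rec = eio.downsample(rec, pp["resample"])
            if pp["baseline"]:
                rec = eio.baseline_correct(rec, tuple(pp["baseline"]))
            if pp["avg_ref"]:
                rec = eio.average_reference(rec)
            processed.append(rec)
        trials = eio.TrialSet(trials=processed, ratings=trials.ratings)
        record("preprocess", [])

    def load_maps() -> gf.TopographyMatrix:
        m = pd.read_csv(out / "peak_maps.tsv", sep="\t")
        o = pd.read_csv(out / "peak_origins.tsv", sep="\t")
        return gf.TopographyMatrix(
            maps=m.to_numpy(), gfp=o["gfp"].to_numpy(),
            origin=o[["recording_id", "sample"]], channel_names=tuple(m.columns),
        )

    def load_templates() -> cs.TemplateSet:
        t = pd.read_csv(out / "templates.tsv", sep="\t")
        side = json.loads((out / "templates.json").read_text())
        return cs.TemplateSet(
            templates=t.to_numpy(), labels=np.zeros(0, dtype=int),
            per_class_gev=np.array(side["per_class_gev"]),
            total_gev=side["total_gev"], channel_names=tuple(t.columns),
        )

    maps = None
    if "gfp" in stages:
        maps = gf.collect_peak_maps(trials, window=cfg["gfp"]["smooth_window"])
        pd.DataFrame(maps.maps, columns=list(maps.channel_names)).to_csv(
            out / "peak_maps.tsv", sep="\t", index=False
        )
        maps.origin.assign(gfp=maps.gfp).to_csv(out / "peak_origins.tsv", sep="\t", index=False)
        record("gfp", [out / "peak_maps.tsv", out / "peak_origins.tsv"])

    templates = None
    if "cluster" in stages:
        ccfg = cs.ClusteringConfig(
            th_gev=cfg["cluster"]["th_gev"],
            th_gmd=cfg["cluster"]["th_gmd"],
            polarity=cfg["cluster"]["polarity"],
        )
        if maps is None:
            maps = load_maps()
        templates = cs.dtaahc(maps, ccfg)
        pd.DataFrame(templates.templates, columns=list(maps.channel_names)).to_csv(
            out / "templates.tsv", sep="\t", index=False
        )
        sidecar = {
            "K": templates.K,
            "per_class_gev": templates.per_class_gev.tolist(),
            "total_gev": templates.total_gev,
            "config": {"th_gev": ccfg.th_gev, "th_gmd": ccfg.th_gmd, "polarity": ccfg.polarity},
            "iteration_log": [[int(k), float(g)] for k, g in templates.iteration_log],
        }
        (out / "templates.json").write_text(json.dumps(sidecar, indent=1))
        record("cluster", [out / "templates.tsv", out / "templates.json"])

    sequences = None
    if "backfit" in stages:
        if templates is None:
            templates = load_templates()
        scfg = bf.SmoothingConfig(
            min_duration=cfg["backfit"]["min_duration"],
            max_passes=cfg["backfit"]["max_passes"],
        )
        sequences = {}
        for rec in trials.trials:
            seq = bf.assign_labels(rec, templates, polarity=cfg["cluster"]["polarity"])
            seq = bf.smooth_labels(seq, scfg, rec, templates, polarity=cfg["cluster"]["polarity"])
            sequences[rec.meta["trial_id"]] = seq
        labels_df = pd.DataFrame(
            {tid: pd.Series(seq.labels) for tid, seq in sequences.items()}
        )
        labels_df.to_csv(out / "labels.tsv", sep="\t", index=False)
        record("backfit", [out / "labels.tsv"])

    feature_table = None
    if "features" in stages:
        if templates is None:
            templates = load_templates()
        if sequences is None:
            ldf = pd.read_csv(out / "labels.tsv", sep="\t")
            sequences = {
                tid: bf.MicrostateSequence(
                    ldf[tid].dropna().to_numpy(dtype=int), templates.K,
                    trials.trials[0].rate, tid,
                )
                for tid in ldf.columns
            }
        fcfg = cfg["features"]
        rows = []
        for rec in trials.trials:
            tid = rec.meta["trial_id"]
            windows = (
                ft.split_windows(rec, fcfg["window_s"]) if fcfg["window_s"] else [rec]
            )
            for w, win in enumerate(windows):
                if fcfg["window_s"]:
                    s0 = win.meta["window_start"]
                    seq = bf.MicrostateSequence(
                        sequences[tid].labels[s0 : s0 + win.n_samples],
                        templates.K, win.rate, tid,
                    )
                else:
                    seq = sequences[tid]
                tf = ft.temporal_features(seq, win, templates)
                tm = ft.transition_matrix(
                    ft.extract_segments(seq), templates.K, level=fcfg["transition_level"]
                )
                vec = ft.build_feature_vector(tf, tm, which="combined")
                row = dict(zip(ft.feature_names(templates.K, "combined"), vec))
                row.update(trial_id=tid, window_id=w)
                for dim in ("valence", "arousal"):
                    row[dim] = trials.ratings.rating(tid, dim)
                rows.append(row)
        feature_table = pd.DataFrame(rows)
        feature_table.to_csv(out / "features.tsv", sep="\t", index=False)
        record("features", [out / "features.tsv"])

    if "stats" in stages:
        if feature_table is None:
            feature_table = pd.read_csv(out / "features.tsv", sep="\t")
        reports = []
        for dim in cfg["stats"]["dimensions"]:
            split = st.split_high_low(trials.ratings, dim)
            reports.append(st.compare_parameters(feature_table, split, fdr=cfg["stats"]["fdr"]))
        report = pd.concat(reports, ignore_index=True)
        report.to_csv(out / "stats.tsv", sep="\t", index=False)
        record("stats", [out / "stats.tsv"])

    if "classify" in stages:
        if feature_table is None:
            feature_table = pd.read_csv(out / "features.tsv", sep="\t")
        if templates is None:
            templates = load_templates()
        kcfg = cfg["classify"]
        dim = kcfg["dimension"]
        split = st.split_high_low(trials.ratings, dim)
        keep = feature_table["trial_id"].isin(split.assignment)
        sub = feature_table[keep]
        which = cfg["features"]["feature_set"]
        names = ft.feature_names(templates.K, which)
        data = cl.LabeledFeatureSet(
            X=sub[names].to_numpy(),
            y=np.array([1 if split.assignment[t] == "high" else 0 for t in sub["trial_id"]]),
            groups=sub["trial_id"].to_numpy(),
            dimension=dim,
        )
        plan = cl.make_folds(data.groups, k=kcfg["folds"], seed=kcfg["seed"], labels=data.y)
        report = cl.evaluate(data, kcfg["classifier"], plan, backend_seed=kcfg["seed"])
        (out / "classification.json").write_text(
            json.dumps(
                {
                    "dimension": dim,
                    "feature_set": which,
                    "classifier": report.classifier,
                    "pooled_accuracy": report.accuracy,
                    "fold_accuracies": report.fold_accuracies,
                    "pooled_counts": vars(report.pooled),
                },
                indent=1,
            )
        )
        record("classify", [out / "classification.json"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def cfg_serializable(cfg: dict) -> dict:
    return json.loads(json.dumps(cfg, default=lambda o: getattr(o, "tolist", lambda: str(o))()))
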