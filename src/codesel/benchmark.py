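"""One-configuration orchestration of the full benchmark.

Runs synth -> aggregate -> encode -> outcome -> patient split -> each
requested selector -> reconstruction evaluation -> supervised case study
-> cross-method comparison, from a single YAML/dict configuration.  A
single master seed deterministically derives a named per-stage seed, so
two runs of the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import case_study as cs
from . import evaluation as ev
from . import records as rec
from . import selectors as sel
from . import synthgen as sg
from .hierarchy import depth_weights_for

logger = logging.getLogger(__name__)

METHODS = ("ls", "mcfs", "aefs", "pfa", "cae", "caeww")

DEFAULT_CONFIG: dict = {
    "master_seed": 0,
    "n_best": 20,
    "train_fraction": 0.67,
    "reference_method": "caeww",
    "methods": list(METHODS),
    "synth": {},                      # SynthConfig overrides
    "cae": {"epochs": 100},           # CAEConfig overrides (full-scale default is 1000)
    "aefs": {},
    "ls": {},
    "mcfs": {},
    "pfa": {},
    "reconstruction": {},             # ReconstructorConfig overrides
    "xgb_grid": {"max_depth": [3], "learning_rate": [0.1],
                 "n_estimators": [100], "min_child_weight": [1]},
    "cv_folds": 3,
}


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)
    version: str = ""
    started: str = ""
    finished: str = ""


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: first 4 bytes of sha256(master:stage), < 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    bad = set(cfg["methods"]) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    return cfg


def _run_selector(method: str, train, cfg: dict, n_best: int, seed: int,
                  depth_weights: np.ndarray) -> sel.SelectionResult:
    if method == "ls":
        return sel.laplacian_score(train, n_best, sel.LSConfig(**cfg["ls"]))
    if method == "mcfs":
        return sel.mcfs_scores(train, n_best, sel.MCFSConfig(**cfg["mcfs"]))
    if method == "aefs":
        return sel.aefs_select(train, n_best, sel.AEFSConfig(**cfg["aefs"]), seed=seed)
    if method == "pfa":
        return sel.pfa_select(train, n_best, sel.PFAConfig(**cfg["pfa"]), seed=seed)
    if method == "cae":
        return sel.cae_select(train, n_best,
                              sel.CAEConfig(weight_adjust=False, **cfg["cae"]), seed=seed)
    if method == "caeww":
        return sel.cae_select(train, n_best,
                              sel.CAEConfig(weight_adjust=True, **cfg["cae"]),
                              seed=seed, feature_weights=depth_weights)
    raise ValueError(method)


def run_benchmark(config, out_dir: str | Path) -> RunManifest:
    """Execute every stage; write the comparison report and manifest.

    Any stage failure aborts with the stage name; the partial manifest
    written so far is attached to the raised error.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["master_seed"])
    manifest = RunManifest(config=cfg, version="0.1.0",
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    stage = "init"
    try:
        stage = "synth"
        seed = derive_seed(master, stage)
        manifest.seeds[stage] = seed
        t0 = time.time()
        synth_cfg = sg.SynthConfig(**{**cfg["synth"], "seed": seed})
        hierarchy = sg.generate_hierarchy(synth_cfg.hierarchy_shape, seed)
        raw, truth = sg.generate_records(synth_cfg, hierarchy)
        logger.info("stage=%s seed=%d wall=%.2fs", stage, seed, time.time() - t0)

        stage = "encode"
        agg = rec.aggregate_records(raw, synth_cfg.window_days)
        matrix = rec.encode_one_hot(agg, hierarchy)
        outcome = sg.generate_outcome(matrix, truth, synth_cfg,
                                      seed=derive_seed(master, "outcome"))
        matrix = matrix.with_outcome(outcome)
        rec.save_matrix(matrix, out / "matrix")
        sg.hierarchy_to_table(hierarchy).to_csv(out / "hierarchy.csv", index=False)
        manifest.artifacts["matrix"] = str(out / "matrix.mtx")
        manifest.artifacts["hierarchy"] = str(out / "hierarchy.csv")

        stage = "split"
        seed = derive_seed(master, stage)
        manifest.seeds[stage] = seed
        train, test = rec.split_by_patient(matrix, cfg["train_fraction"], seed)

        dweights = np.asarray(depth_weights_for(hierarchy, matrix.feature_codes))
        n_best = min(int(cfg["n_best"]), matrix.n_features)

        report_rows: dict[str, dict] = {}
        selections: dict[str, np.ndarray] = {}
        shap_by_method: dict[str, np.ndarray] = {}
        scores_by_method: dict[str, np.ndarray] = {}
        preds_by_method: dict[str, np.ndarray] = {}

        methods = list(cfg["methods"])
        reference = cfg["reference_method"]
        ordered = ([reference] + [m for m in methods if m != reference]
                   if reference in methods else methods)

        for method in ordered:
            stage = f"select:{method}"
            seed = derive_seed(master, stage)
            manifest.seeds[stage] = seed
            t0 = time.time()
            result = _run_selector(method, train, cfg, n_best, seed, dweights)
            selections[method] = result.selected
            logger.info("stage=%s seed=%d wall=%.2fs n_selected=%d",
                        stage, seed, time.time() - t0, result.selected.size)

            stage = f"recon:{method}"
            seed = derive_seed(master, stage)
            manifest.seeds[stage] = seed
            recon = ev.evaluate_selection(
                train, test, result.selected, seed,
                ev.ReconstructorConfig(**cfg["reconstruction"]))

            stage = f"case_study:{method}"
            seed = derive_seed(master, stage)
            manifest.seeds[stage] = seed
            ref_scores = scores_by_method.get(reference)
            ref_preds = preds_by_method.get(reference)
            report, scores, preds = cs.run_case_study(
                train, test, result.selected, seed,
                cv_folds=cfg["cv_folds"], grid=cfg["xgb_grid"],
                reference_scores=None if method == reference else ref_scores,
                reference_preds=None if method == reference else ref_preds,
                feature_codes=matrix.feature_codes, hierarchy=hierarchy)
            scores_by_method[method] = scores
            preds_by_method[method] = preds
            shap_by_method[method] = report.shap_mean_abs

            report_rows[method] = {
                "n_selected": int(result.selected.size),
                "mean_accuracy": recon.mean_accuracy,
                "mean_bce": recon.mean_bce,
                "baseline_mean_accuracy": recon.baseline_mean_accuracy,
                "baseline_mean_bce": recon.baseline_mean_bce,
                "t_test_p": recon.t_test_p,
                "accuracy": report.accuracy,
                "f1": report.f1,
                "auc_roc": report.auc_roc,
                "delong_p_vs_reference": report.delong_p_vs_reference,
                "mcnemar_p_vs_reference": report.mcnemar_p_vs_reference,
                "mean_abs_shap": float(np.mean(report.shap_mean_abs)),
                "mean_selected_depth": report.mean_selected_depth,
            }

        stage = "comparison"
        if len(selections) >= 2 and reference in selections:
            comparison = cs.depth_and_importance_comparison(
                selections, matrix.feature_codes, hierarchy,
                shap_values=shap_by_method, reference=reference)
            comparison.to_csv(out / "depth_comparison.csv")
            manifest.artifacts["depth_comparison"] = str(out / "depth_comparison.csv")

        report_path = out / "comparison_report.json"
        with open(report_path, "w") as fh:
            json.dump(report_rows, fh, indent=2, sort_keys=True)
        manifest.artifacts["comparison_report"] = str(report_path)

        pd.DataFrame(report_rows).T.rename_axis("method").to_csv(out / "comparison_report.csv")
        manifest.artifacts["comparison_csv"] = str(out / "comparison_report.csv")
    except Exception as exc:
        raise RuntimeError(f"benchmark stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"config": manifest.config, "seeds": manifest.seeds,
                   "artifacts": manifest.artifacts, "version": manifest.version,
                   "started": manifest.started, "finished": manifest.finished},
                  fh, indent=2, sort_keys=True)
    manifest.artifacts["manifest"] = str(manifest_path)
    for path in manifest.artifacts.values():
        assert Path(path).exists()
    return manifest
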