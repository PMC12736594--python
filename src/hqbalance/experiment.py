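"""Config-driven experiment orchestration.

``run_experiment`` executes the full pipeline (simulate -> features ->
label -> models/ablations -> evaluation -> interpretability), writes every
artefact (feature table, OOF predictions, report JSONs, report-table CSVs,
importance and partial-dependence outputs) and returns a manifest with
per-stage wall-clock timings.  ``run_replicates`` repeats the modeling and
evaluation over several master seeds and aggregates seed-level metrics,
which is how stochastic headline numbers are reported.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig, RuleThresholds, SimulationConfig
from .evaluation import classification_metrics, evaluate_oof, stratified_report
from .interpret import partial_dependence_curve, permutation_importance_report
from .models import (CalibratedTrialClassifier, make_grouped_folds,
                     run_ablation_suite)
from .simulate import generate_dataset

log = logging.getLogger("hqbalance")

ABLATION_ORDER = ("full_ml", "no_label_ml", "label_only_ml", "calibrated_rule")


@dataclass
class ExperimentManifest:
    config: dict
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def write_report_tables(reports: dict[str, dict], outdir: Path) -> list[Path]:
    """CSV summary tables of the experiment results.

    * ablation table: one row per configuration with the headline metrics;
    * extended comparison: full model vs logistic baseline per metric;
    * per-speed table: one row per band for the full model;
    * diagnostic-index table: the seven confusion-derived indices.
    Numbers are printed at 3 decimals with CIs as "lo-hi" strings; the raw
    floats live in the report JSONs.
    """
    paths = []

    rows = []
    for name in ABLATION_ORDER:
        if name not in reports:
            continue
        r = reports[name]
        row = {"configuration": name}
        for m, entry in r["metrics"].items():
            lo, hi = entry["ci"]
            row[m] = _fmt(entry["value"])
            row[f"{m}_ci"] = f"{_fmt(lo)}-{_fmt(hi)}"
        cal = r["calibration"]
        row["calibration_slope"] = _fmt(cal["slope"])
        row["calibration_intercept"] = _fmt(cal["intercept"])
        nb = pd.DataFrame(r["net_benefit"])
        at20 = nb.loc[(nb.threshold - 0.20).abs().idxmin(), "net_benefit"]
        row["net_benefit_at_0.20"] = _fmt(at20)
        rows.append(row)
    p = outdir / "table_ablations.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    paths.append(p)

    if "full_ml" in reports and "logistic" in reports:
        rows = []
        for m in ("roc_auc", "balanced_accuracy", "pr_auc", "f1", "brier"):
            g = reports["full_ml"]["metrics"][m]
            l = reports["logistic"]["metrics"][m]
            rows.append({
                "metric": m,
                "gradient_boosting": _fmt(g["value"]),
                "gradient_boosting_ci": f"{_fmt(g['ci'][0])}-{_fmt(g['ci'][1])}",
                "logistic": _fmt(l["value"]),
                "delta": _fmt(g["value"] - l["value"]),
            })
        p = outdir / "table_extended_performance.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths.append(p)

    if "full_ml" in reports and "per_speed" in reports["full_ml"]:
        rows = []
        for band, sub in sorted(reports["full_ml"]["per_speed"].items()):
            if "metrics" not in sub:
                continue
            m = sub["metrics"]
            rows.append({"speed_band": band, "n": sub["n"],
                         **{k: _fmt(v) for k, v in m.items()}})
        p = outdir / "table_by_speed.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths.append(p)

    if "full_ml" in reports:
        di = reports["full_ml"]["diagnostic_indices"]
        order = ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                 "balanced_accuracy", "f1")
        p = outdir / "table_diagnostic_indices.csv"
        pd.DataFrame([{"metric": k, "value": _fmt(di[k])} for k in order]
                     ).to_csv(p, index=False)
        paths.append(p)
    return paths


def run_experiment(config: SimulationConfig | None = None,
                   outdir: str | Path = "hqbalance_run",
                   seed: int | None = None,
                   model_config: ModelConfig | None = None,
                   thresholds: RuleThresholds | None = None,
                   n_boot: int = 2000,
                   pd_features: tuple[str, ...] = ("hq_dyn",
                                                   "lsi_knee_moment",
                                                   "cci_early_stance"),
                   ) -> ExperimentManifest:
    """Run the full pipeline once and write all artefacts to ``outdir``."""
    config = config or SimulationConfig()
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    thresholds = thresholds or RuleThresholds()
    model_config = model_config or ModelConfig(seed=config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = ExperimentManifest(config=json.loads(config.model_dump_json()),
                                  seed=config.seed)

    def _stage(name):
        t0 = time.perf_counter()

        def _done(paths=()):
            manifest.timings_s[name] = round(time.perf_counter() - t0, 3)
            for p in paths:
                manifest.outputs[Path(p).name] = str(p)
            log.info("stage %s done in %.1fs", name, manifest.timings_s[name])
        return _done

    done = _stage("simulate")
    bundle = generate_dataset(config, thresholds)
    table_path = outdir / "feature_table.csv"
    bundle.table.to_csv(table_path, index=False)
    done([table_path])

    done = _stage("models")
    suite = run_ablation_suite(bundle.table, seed=config.seed,
                               n_folds=model_config.n_folds,
                               thresholds=thresholds)
    oof_paths = []
    for name, oof in suite.items():
        p = outdir / f"oof_{name}.csv"
        oof.to_csv(p, index=False)
        oof_paths.append(p)
    done(oof_paths)

    done = _stage("evaluate")
    reports = {}
    for name, oof in suite.items():
        reports[name] = evaluate_oof(oof, threshold=model_config.classification_threshold,
                                     n_boot=n_boot, seed=config.seed)
    report_path = outdir / "reports.json"
    report_path.write_text(json.dumps(reports, indent=2, default=float))
    table_paths = write_report_tables(reports, outdir)
    done([report_path, *table_paths])

    done = _stage("interpret")
    folds = make_grouped_folds(bundle.table["subject_id"].to_numpy(),
                               model_config.n_folds, config.seed)
    model = CalibratedTrialClassifier(random_state=config.seed)
    train = folds != 0
    y = bundle.table["label_observed"].to_numpy()
    model.fit(bundle.table.loc[train], y[train],
              groups=bundle.table.loc[train, "subject_id"].to_numpy())
    holdout = bundle.table.loc[~train]
    imp = permutation_importance_report(
        model, holdout[list(model.feature_names_)], y[~train],
        seed=config.seed)
    imp_path = outdir / "permutation_importance.csv"
    imp.to_csv(imp_path, index=False)
    pd_paths = []
    background = bundle.table.sample(n=min(200, len(bundle.table)),
                                     random_state=config.seed)
    for feat in pd_features:
        lo, hi = bundle.table[feat].quantile([0.02, 0.98])
        curve = partial_dependence_curve(model, background, feat,
                                         np.linspace(lo, hi, 25))
        p = outdir / f"partial_dependence_{feat}.csv"
        curve.to_csv(p, index=False)
        pd_paths.append(p)
    done([imp_path, *pd_paths])

    manifest.to_json(outdir / "manifest.json")
    manifest.outputs["manifest.json"] = str(outdir / "manifest.json")
    return manifest


def run_replicates(n_seeds: int = 10, base_seed: int = 0,
                   config: SimulationConfig | None = None,
                   thresholds: RuleThresholds | None = None,
                   include_logistic: bool = True) -> pd.DataFrame:
    """Seed-level headline metrics for every configuration.

    Returns one row per (seed, configuration) with ROC-AUC, PR-AUC,
    balanced accuracy, F1, Brier and per-speed-band ROC-AUCs; stochastic
    headline numbers are means over these rows.
    """
    base = config or SimulationConfig()
    rows = []
    for i in range(n_seeds):
        seed = int(base_seed + i)
        cfg = base.model_copy(update={"seed": seed})
        bundle = generate_dataset(cfg, thresholds)
        suite = run_ablation_suite(bundle.table, seed=seed,
                                   thresholds=thresholds,
                                   include_logistic=include_logistic)
        for name, oof in suite.items():
            row = {"seed": seed, "configuration": name,
                   "prevalence_latent": bundle.table["label_latent"].mean()}
            row.update(classification_metrics(oof["prob"], oof["label_observed"]))
            for band, sub in stratified_report(oof).items():
                if "metrics" in sub:
                    row[f"roc_auc_band{band}"] = sub["metrics"]["roc_auc"]
            rows.append(row)
    return pd.DataFrame(rows)
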