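"""Discrimination, diagnostic, calibration and decision-curve evaluation.

All quantities operate on out-of-fold probabilities.  Confidence intervals
use a cluster bootstrap that resamples *subjects* with replacement (keeping
all of a subject's trials together), matching the subject-wise design of
the cross-validation.  Calibration diagnostics comprise logistic
recalibration slope/intercept, expected and maximum calibration error on
ten equal-width reliability bins, the Murphy decomposition of the Brier
score (reliability - resolution + uncertainty) on the same bins, and
Spiegelhalter's Z.  Decision-curve net benefit is
``TP/n - FP/n * t/(1-t)`` against treat-all and treat-none references.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (average_precision_score, brier_score_loss,
                             roc_auc_score)


def _as_arrays(probs, labels):
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must be aligned")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return probs, labels


def confusion_counts(probs, labels, threshold: float = 0.5
                     ) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) classifying positive when prob >= threshold."""
    probs, labels = _as_arrays(probs, labels)
    pred = probs >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def confusion_indices(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Diagnostic indices from confusion-matrix counts.

    Zero-denominator indices are returned as NaN (flagged, not raised).
    Values are unrounded; round only at reporting.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
        "balanced_accuracy": (sens + spec) / 2.0,
        "f1": _ratio(2 * tp, 2 * tp + fp + fn),
        "lr_pos": _ratio(sens, 1.0 - spec) if spec == spec else float("nan"),
        "lr_neg": _ratio(1.0 - sens, spec) if spec == spec else float("nan"),
    }
    return out


def classification_metrics(probs, labels, threshold: float = 0.5
                           ) -> dict[str, float]:
    """ROC-AUC, PR-AUC, balanced accuracy, F1 and Brier score."""
    probs, labels = _as_arrays(probs, labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes are required for AUC metrics")
    tp, fp, tn, fn = confusion_counts(probs, labels, threshold)
    ci = confusion_indices(tp, fp, tn, fn)
    return {
        "roc_auc": float(roc_auc_score(labels, probs)),
        "pr_auc": float(average_precision_score(labels, probs)),
        "balanced_accuracy": ci["balanced_accuracy"],
        "f1": ci["f1"],
        "brier": float(brier_score_loss(labels, probs)),
    }


def calibration_report(probs, labels, n_bins: int = 10) -> dict[str, float]:
    """Calibration slope/intercept, ECE/MCE, Murphy decomposition, and Z.

    Slope and intercept come from a logistic recalibration fit of the
    outcomes on logit(probs) (Cox calibration).  ECE/MCE and the Brier
    decomposition use ``n_bins`` equal-width bins; empty bins carry zero
    weight.  Spiegelhalter's Z is
    ``sum((y-p)(1-2p)) / sqrt(sum((1-2p)^2 p(1-p)))``.
    """
    probs, labels = _as_arrays(probs, labels)
    n = probs.size
    clipped = np.clip(probs, 1e-6, 1.0 - 1e-6)
    logit = np.log(clipped / (1.0 - clipped))
    if np.unique(labels).size < 2:
        slope = intercept = float("nan")
    else:
        lr = LogisticRegression(C=float("inf"), max_iter=5000)
        lr.fit(logit.reshape(-1, 1), labels)
        slope = float(lr.coef_[0, 0])
        intercept = float(lr.intercept_[0])

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    ece = 0.0
    mce = 0.0
    reliability = 0.0
    resolution = 0.0
    base_rate = labels.mean()
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        w = mask.mean()
        p_bin = probs[mask].mean()
        y_bin = labels[mask].mean()
        gap = abs(p_bin - y_bin)
        ece += w * gap
        mce = max(mce, gap)
        reliability += w * (p_bin - y_bin) ** 2
        resolution += w * (y_bin - base_rate) ** 2
    uncertainty = base_rate * (1.0 - base_rate)

    num = np.sum((labels - probs) * (1.0 - 2.0 * probs))
    den = np.sqrt(np.sum((1.0 - 2.0 * probs) ** 2 * probs * (1.0 - probs)))
    z = float(num / den) if den > 0 else 0.0
    return {
        "slope": slope,
        "intercept": intercept,
        "ece": float(ece),
        "mce": float(mce),
        "brier_reliability": float(reliability),
        "brier_resolution": float(resolution),
        "brier_uncertainty": float(uncertainty),
        "binned_brier": float(reliability - resolution + uncertainty),
        "spiegelhalter_z": z,
        "spiegelhalter_p": float(2.0 * stats.norm.sf(abs(z))),
        "n": int(n),
    }


def decision_curve(probs, labels, thresholds=None) -> pd.DataFrame:
    """Net-benefit curves for the model, treat-all, and treat-none.

    ``NB(t) = TP(t)/n - FP(t)/n * t/(1-t)`` classifying positive at
    ``prob >= t``; treat-all uses the prevalence closed form.
    """
    probs, labels = _as_arrays(probs, labels)
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 0.505, 0.01), 4)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = probs.size
    pi = labels.mean()
    rows = []
    for t in thresholds:
        tp, fp, _, _ = confusion_counts(probs, labels, t)
        odds = t / (1.0 - t)
        rows.append({
            "threshold": t,
            "net_benefit": tp / n - fp / n * odds,
            "treat_all": pi - (1.0 - pi) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


_DEFAULT_METRICS = ("roc_auc", "pr_auc", "balanced_accuracy", "f1", "brier")


def _metric_values(probs, labels, threshold, metrics):
    vals = classification_metrics(probs, labels, threshold)
    return {m: vals[m] for m in metrics}


def bootstrap_cis(oof: pd.DataFrame, metrics=_DEFAULT_METRICS,
                  n_boot: int = 2000, seed: int | None = 0,
                  threshold: float = 0.5) -> dict[str, tuple[float, float]]:
    """Subject-level (cluster) bootstrap percentile CIs for each metric.

    Subjects are resampled with replacement, carrying all their trials.
    Resamples with a single class are skipped; if more than 10% are
    skipped a warning is emitted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    subjects = oof["subject_id"].to_numpy()
    unique = pd.unique(subjects)
    by_subject = {s: np.flatnonzero(subjects == s) for s in unique}
    probs = oof["prob"].to_numpy()
    labels = oof["label_observed"].to_numpy()
    samples: dict[str, list[float]] = {m: [] for m in metrics}
    skipped = 0
    for _ in range(n_boot):
        draw = rng.choice(unique.size, size=unique.size, replace=True)
        idx = np.concatenate([by_subject[unique[j]] for j in draw])
        if np.unique(labels[idx]).size < 2:
            skipped += 1
            continue
        vals = _metric_values(probs[idx], labels[idx], threshold, metrics)
        for m in metrics:
            samples[m].append(vals[m])
    if skipped > 0.1 * n_boot:
        warnings.warn(f"{skipped}/{n_boot} bootstrap resamples were "
                      "single-class and skipped", RuntimeWarning)
    return {m: (float(np.percentile(samples[m], 2.5)),
                float(np.percentile(samples[m], 97.5)))
            for m in metrics}


def evaluate_oof(oof: pd.DataFrame, threshold: float = 0.5,
                 n_boot: int = 2000, seed: int | None = 0,
                 n_bins: int = 10, with_strata: bool = True) -> dict:
    """Full evaluation report for one out-of-fold prediction set."""
    probs = oof["prob"].to_numpy()
    labels = oof["label_observed"].to_numpy()
    point = classification_metrics(probs, labels, threshold)
    cis = bootstrap_cis(oof, n_boot=n_boot, seed=seed, threshold=threshold)
    tp, fp, tn, fn = confusion_counts(probs, labels, threshold)
    report = {
        "n": int(len(oof)),
        "threshold": threshold,
        "metrics": {m: {"value": point[m], "ci": list(cis[m])} for m in point},
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        "diagnostic_indices": confusion_indices(tp, fp, tn, fn),
        "calibration": calibration_report(probs, labels, n_bins),
        "net_benefit": decision_curve(probs, labels).to_dict(orient="list"),
    }
    if with_strata and "speed_band" in oof:
        report["per_speed"] = {
            int(band): sub
            for band, sub in stratified_report(oof, threshold=threshold,
                                               n_bins=n_bins).items()
        }
    return report


def stratified_report(oof: pd.DataFrame, by: str = "speed_band",
                      threshold: float = 0.5, n_bins: int = 10) -> dict:
    """Per-stratum metric sets (no bootstrap, flags single-class strata)."""
    out = {}
    for key, grp in oof.groupby(by):
        probs = grp["prob"].to_numpy()
        labels = grp["label_observed"].to_numpy()
        tp, fp, tn, fn = confusion_counts(probs, labels, threshold)
        entry: dict = {
            "n": int(len(grp)),
            "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
            "diagnostic_indices": confusion_indices(tp, fp, tn, fn),
        }
        if np.unique(labels).size < 2:
            entry["flag"] = "single-class stratum; AUC metrics omitted"
        else:
            entry["metrics"] = classification_metrics(probs, labels, threshold)
            entry["calibration"] = calibration_report(probs, labels, n_bins)
        out[key] = entry
    return out
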