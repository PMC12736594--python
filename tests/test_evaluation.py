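"""Metrics, diagnostic indices, calibration diagnostics, decision curves,
bootstrap confidence intervals."""

import numpy as np
import pandas as pd
import pytest

from hqbalance.evaluation import (bootstrap_cis, calibration_report,
                                  classification_metrics, confusion_counts,
                                  confusion_indices, decision_curve,
                                  evaluate_oof, stratified_report)


def _pairwise_auc(probs, labels):
    """Exhaustive pair-enumeration oracle (ties credit one half)."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        m = classification_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert m["roc_auc"] == 1.0 and m["brier"] == 0.0

    def test_four_point_example_matches_pair_enumeration(self):
        probs = [0.9, 0.8, 0.4, 0.2]
        labels = [1, 0, 1, 0]
        m = classification_metrics(probs, labels)
        assert m["roc_auc"] == pytest.approx(0.75)
        assert m["roc_auc"] == pytest.approx(_pairwise_auc(probs, labels))

    def test_uninformative_constant_probabilities(self):
        m = classification_metrics([0.5] * 4, [1, 0, 1, 0])
        assert m["roc_auc"] == pytest.approx(0.5)
        assert m["brier"] == pytest.approx(0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([0.1, 0.9], [1, 1])


class TestConfusionIndices:
    def test_reference_confusion_matrix_worked_example(self):
        ci = confusion_indices(tp=249, fp=10, tn=292, fn=22)
        assert round(ci["sensitivity"], 3) == 0.919
        assert round(ci["specificity"], 3) == 0.967
        assert round(ci["ppv"], 3) == 0.961
        assert round(ci["npv"], 3) == 0.930
        assert round(ci["balanced_accuracy"], 3) == 0.943
        assert round(ci["f1"], 3) == 0.940
        assert round(ci["lr_pos"]) == 28
        assert round(ci["lr_neg"], 2) == 0.08

    def test_perfect_counts(self):
        ci = confusion_indices(50, 0, 50, 0)
        for key in ("sensitivity", "specificity", "ppv", "npv",
                    "accuracy", "balanced_accuracy", "f1"):
            assert ci[key] == 1.0

    def test_coin_flip_counts(self):
        ci = confusion_indices(50, 50, 50, 50)
        for key in ("sensitivity", "specificity", "ppv", "npv"):
            assert ci[key] == pytest.approx(0.5)

    def test_zero_denominators_flagged_not_raised(self):
        ci = confusion_indices(0, 0, 10, 5)
        assert np.isnan(ci["ppv"])
        with pytest.raises(ValueError):
            confusion_indices(-1, 0, 0, 0)


class TestCalibration:
    def test_brier_decomposition_identity(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(0.01, 0.99, 500)
        labels = (rng.random(500) < probs).astype(int)
        rep = calibration_report(probs, labels)
        # identity holds on the *binned* Brier estimator
        edges = np.linspace(0, 1, 11)
        idx = np.clip(np.digitize(probs, edges[1:-1]), 0, 9)
        binned = np.mean([(probs[idx == b].mean() - labels[i]) ** 2
                          for b in range(10) if (idx == b).any()
                          for i in np.flatnonzero(idx == b)])
        assert rep["binned_brier"] == pytest.approx(
            rep["brier_reliability"] - rep["brier_resolution"]
            + rep["brier_uncertainty"], abs=1e-12)
        assert rep["binned_brier"] == pytest.approx(binned, abs=1e-12)

    def test_perfectly_calibrated_bins_have_zero_ece(self):
        probs = np.repeat([0.25, 0.75], 200)
        labels = np.concatenate([np.tile([1, 0, 0, 0], 50),
                                 np.tile([1, 1, 1, 0], 50)])
        rep = calibration_report(probs, labels)
        assert rep["ece"] == pytest.approx(0.0, abs=1e-12)
        assert rep["brier_reliability"] == pytest.approx(0.0, abs=1e-12)

    def test_spiegelhalter_z_zero_at_half(self):
        probs = np.full(100, 0.5)
        labels = np.tile([0, 1], 50)
        assert calibration_report(probs, labels)["spiegelhalter_z"] == 0.0


class TestDecisionCurve:
    def test_arithmetic_oracle(self):
        # 30 TP and 10 FP at t=0.2 among n=100 -> NB = 0.30 - 0.10*0.25
        probs = np.concatenate([np.full(30, 0.9), np.full(10, 0.9),
                                np.full(20, 0.1), np.full(40, 0.1)])
        labels = np.concatenate([np.ones(30), np.zeros(10),
                                 np.ones(20), np.zeros(40)])
        nb = decision_curve(probs, labels, thresholds=[0.2])
        assert nb.net_benefit.iloc[0] == pytest.approx(0.275)

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        labels = np.tile([0, 1], 50)
        nb = decision_curve(labels.astype(float) * 0.98 + 0.01, labels)
        assert np.allclose(nb.net_benefit, 0.5)

    def test_treat_all_closed_form(self):
        labels = np.tile([0, 1], 50)
        probs = np.random.default_rng(1).uniform(size=100)
        nb = decision_curve(probs, labels)
        t = nb.threshold.to_numpy()
        assert np.allclose(nb.treat_all, 0.5 - 0.5 * t / (1 - t), atol=1e-12)
        assert np.allclose(nb.treat_none, 0.0)
        # treat-all crosses zero exactly at the prevalence threshold
        assert abs(np.interp(0.5, t, nb.treat_all)) < 1e-12

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[1.0])


class TestBootstrap:
    @staticmethod
    def _oof(probs, labels, subjects):
        return pd.DataFrame({"subject_id": subjects, "prob": probs,
                             "label_observed": labels})

    def test_degenerate_perfect_predictions_collapse(self):
        labels = np.tile([0, 1], 30)
        oof = self._oof(labels.astype(float), labels,
                        np.repeat(np.arange(20), 3))
        cis = bootstrap_cis(oof, metrics=("roc_auc", "brier"), n_boot=200,
                            seed=0)
        assert cis["roc_auc"] == (1.0, 1.0)
        assert cis["brier"] == (0.0, 0.0)

    def test_point_estimate_within_bootstrap_range(self):
        rng = np.random.default_rng(2)
        subjects = np.repeat(np.arange(50), 3)
        probs = rng.uniform(size=150)
        labels = (rng.random(150) < probs).astype(int)
        oof = self._oof(probs, labels, subjects)
        cis = bootstrap_cis(oof, metrics=("roc_auc",), n_boot=400, seed=2)
        point = classification_metrics(probs, labels)["roc_auc"]
        lo, hi = cis["roc_auc"]
        assert lo <= point <= hi

    def test_known_truth_coverage(self):
        """95% cluster-bootstrap CI covers the population AUC >=90% of runs."""
        rng = np.random.default_rng(3)
        n_subj, per = 200, 3
        p = np.repeat(rng.uniform(0.1, 0.9, n_subj), per)
        pos_w = p[:, None] * (1 - p[None, :])
        gt = (p[:, None] > p[None, :]) + 0.5 * (p[:, None] == p[None, :])
        true_auc = float((pos_w * gt).sum() / pos_w.sum())
        covered = 0
        n_rep = 60
        for _ in range(n_rep):
            labels = (rng.random(p.size) < p).astype(int)
            oof = self._oof(p, labels, np.repeat(np.arange(n_subj), per))
            lo, hi = bootstrap_cis(oof, metrics=("roc_auc",), n_boot=300,
                                   seed=int(rng.integers(2**31)))["roc_auc"]
            covered += lo <= true_auc <= hi
        assert covered / n_rep >= 0.90

    def test_n_boot_validated(self):
        oof = self._oof([0.2, 0.8], [0, 1], ["a", "b"])
        with pytest.raises(ValueError):
            bootstrap_cis(oof, n_boot=10)


class TestStratifiedReport:
    def test_whole_sample_stratum_matches_unstratified(self):
        rng = np.random.default_rng(4)
        oof = pd.DataFrame({
            "subject_id": np.repeat(np.arange(40), 3),
            "prob": rng.uniform(size=120),
            "label_observed": rng.integers(0, 2, 120),
            "speed_band": np.zeros(120, dtype=int)})
        rep = stratified_report(oof)
        assert set(rep) == {0}
        expected = classification_metrics(oof.prob, oof.label_observed)
        assert rep[0]["metrics"] == expected

    def test_single_class_stratum_flagged(self):
        oof = pd.DataFrame({"subject_id": ["a", "b"], "prob": [0.2, 0.9],
                            "label_observed": [1, 1], "speed_band": [0, 0]})
        rep = stratified_report(oof)
        assert "flag" in rep[0] and "metrics" not in rep[0]

    def test_full_report_structure(self, small_bundle):
        from hqbalance.models import run_ablation_suite
        suite = run_ablation_suite(small_bundle.table, seed=11,
                                   include_logistic=False)
        rep = evaluate_oof(suite["full_ml"], n_boot=200, seed=0)
        assert rep["confusion"]["tp"] + rep["confusion"]["fp"] \
            + rep["confusion"]["tn"] + rep["confusion"]["fn"] == rep["n"]
        assert set(rep["metrics"]) == {"roc_auc", "pr_auc",
                                       "balanced_accuracy", "f1", "brier"}
        assert len(rep["per_speed"]) == 3
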