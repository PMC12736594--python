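"""Shared fixtures.

The expensive session fixture ``replicate_study`` runs the complete
modeling study (default cohort, subject-wise 5-fold CV, all ablation
configurations, fold-averaged permutation importance and partial
dependence) over ten master seeds; the headline stochastic checks all
consume it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from hqbalance.config import SimulationConfig
from hqbalance.evaluation import classification_metrics
from hqbalance.interpret import (partial_dependence_curve,
                                 permutation_importance_report)
from hqbalance.models import (CalibratedTrialClassifier, fit_predict_oof,
                              make_grouped_folds, run_ablation_suite)
from hqbalance.simulate import DatasetBundle, generate_dataset

N_STUDY_SEEDS = 10


def measurement_free_config(**overrides) -> SimulationConfig:
    """Default config with the entire measurement layer switched off."""
    base = dict(measurement_noise_sd=0.0, channel_gain_sd=0.0,
                speed_lsi_read_bias=[1.0, 1.0, 1.0],
                speed_ham_gain_bias=[1.0, 1.0, 1.0])
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_bundle() -> DatasetBundle:
    return generate_dataset(SimulationConfig(n_subjects=20, n_trials_total=70,
                                             seed=11))


@pytest.fixture(scope="session")
def noise_free_bundle() -> DatasetBundle:
    return generate_dataset(
        measurement_free_config(n_subjects=30, n_trials_total=100, seed=7))


@dataclass
class StudyResults:
    metrics: pd.DataFrame        # one row per (seed, configuration)
    importance: pd.DataFrame     # feature x seed, fold-averaged, normalised
    pd_lsi: np.ndarray           # seeds x 3 PD values at LSI -20/0/+20


@pytest.fixture(scope="session")
def replicate_study() -> StudyResults:
    rows, imps, pd_vals = [], [], []
    for seed in range(N_STUDY_SEEDS):
        bundle = generate_dataset(SimulationConfig(seed=seed))
        table = bundle.table
        suite = run_ablation_suite(table, seed=seed)
        for name, oof in suite.items():
            row = {"seed": seed, "configuration": name,
                   "prevalence_latent": table["label_latent"].mean()}
            row.update(classification_metrics(oof["prob"],
                                              oof["label_observed"]))
            for band in sorted(oof["speed_band"].unique()):
                sub = oof[oof["speed_band"] == band]
                row[f"roc_auc_band{band}"] = classification_metrics(
                    sub["prob"], sub["label_observed"])["roc_auc"]
            rows.append(row)

        y = table["label_observed"].to_numpy()
        folds = make_grouped_folds(table["subject_id"].to_numpy(), 5, seed)
        _, models = fit_predict_oof(
            table, y, folds, CalibratedTrialClassifier(random_state=seed),
            return_models=True)
        per_fold = []
        curves = []
        background = table.sample(n=200, random_state=seed)
        for k, model in models.items():
            holdout = table.loc[folds == k]
            imp = permutation_importance_report(
                model, holdout[list(model.feature_names_)], y[folds == k],
                seed=seed)
            per_fold.append(imp.set_index("feature")["normalized_importance"])
            curves.append(partial_dependence_curve(
                model, background, "lsi_knee_moment",
                [-20.0, 0.0, 20.0])["partial_dependence"].to_numpy())
        imps.append(pd.concat(per_fold, axis=1).mean(axis=1))
        pd_vals.append(np.mean(curves, axis=0))
    return StudyResults(metrics=pd.DataFrame(rows),
                        importance=pd.concat(imps, axis=1),
                        pd_lsi=np.asarray(pd_vals))
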