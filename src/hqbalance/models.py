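"""Classifiers, subject-wise grouped cross-validation, and ablations.

Estimators follow scikit-learn conventions (``fit``/``predict_proba``,
``get_params``, fitted attributes with trailing underscores) and compose
with sklearn tooling.  ``fit`` accepts a ``groups`` argument carrying
subject identifiers: probability calibration is fitted on a subject-grouped
hold-out split of the training data, never on test subjects.

The ablation ladder comprises four configurations on identical folds: the
full-feature gradient-boosted model, a model without the three
label-defining features (H:Qdyn, knee-moment LSI, CCI), a model with only
those three, and the isotonic-calibrated continuous rule score.  A
calibrated logistic regression serves as the linear baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .config import FEATURE_COLUMNS, RuleThresholds
from .labeling import rule_margin_score

LABEL_FEATURES = ("hq_dyn", "lsi_knee_moment", "cci_early_stance")

FEATURE_MASKS: dict[str, tuple[str, ...]] = {
    "full": FEATURE_COLUMNS,
    "no_label_features": tuple(c for c in FEATURE_COLUMNS
                               if c not in LABEL_FEATURES),
    "label_features_only": LABEL_FEATURES,
}


class _InSampleCalibrated:
    """Base model + isotonic map pair (small-sample calibration fallback)."""

    def __init__(self, base, iso):
        self.base = base
        self.iso = iso

    def predict_proba(self, X):
        p = self.iso.predict(self.base.predict_proba(X)[:, 1])
        return np.column_stack([1.0 - p, p])


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    if X.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(
            "array input must have the canonical 8 feature columns; "
            "pass a DataFrame for masked configurations")
    return pd.DataFrame(X, columns=list(FEATURE_COLUMNS))


class CalibratedTrialClassifier(ClassifierMixin, BaseEstimator):
    """Gradient-boosted or logistic trial classifier with isotonic calibration.

    Parameters mirror the study configuration: a gradient-boosted tree
    ensemble (400 shallow trees, learning rate 0.05, 0.9 subsampling, leaf
    size 20 -- chosen for stable probability estimates at n~600 with noisy
    labels), or a standardised weak-L2 logistic regression.  With ``calibration="isotonic"``,
    calibration is cross-fitted within the training data: subject-grouped
    inner folds (``round(1/calib_fraction)`` of them, so each isotonic map
    is estimated on a grouped ``calib_fraction`` hold-out it was never
    trained on) and the per-fold calibrated models are averaged at
    prediction time.  Calibration never sees test subjects.

    Attributes
    ----------
    base_estimator_ : fitted underlying sklearn model
        (a :class:`CalibratedClassifierCV` when calibrated)
    feature_names_ : tuple of the columns actually used
    """

    def __init__(self, family: str = "gbdt", feature_mask: str = "full",
                 calibration: str = "isotonic", calib_fraction: float = 0.2,
                 n_estimators: int = 400, max_depth: int = 2,
                 learning_rate: float = 0.05, subsample: float = 0.9,
                 min_samples_leaf: int = 20,
                 logistic_c: float = 1000.0, random_state: int | None = None):
        self.family = family
        self.feature_mask = feature_mask
        self.calibration = calibration
        self.calib_fraction = calib_fraction
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.min_samples_leaf = min_samples_leaf
        self.logistic_c = logistic_c
        self.random_state = random_state

    def _make_base(self):
        if self.family == "gbdt":
            # a non-trivial leaf size keeps the trees from isolating the
            # stochastically flipped labels near the decision boundary
            return GradientBoostingClassifier(
                n_estimators=self.n_estimators, max_depth=self.max_depth,
                learning_rate=self.learning_rate, subsample=self.subsample,
                min_samples_leaf=self.min_samples_leaf,
                random_state=self.random_state)
        if self.family == "logistic":
            return make_pipeline(
                StandardScaler(),
                LogisticRegression(C=self.logistic_c, max_iter=5000))
        raise ValueError(f"unknown family {self.family!r}")

    def fit(self, X, y, groups=None):
        X = _as_frame(X)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("training data contains a single class")
        self.feature_names_ = FEATURE_MASKS[self.feature_mask]
        Xm = X.loc[:, list(self.feature_names_)].to_numpy(dtype=float)
        base = self._make_base()
        if self.calibration == "isotonic":
            if groups is None:
                raise ValueError("isotonic calibration requires groups "
                                 "(subject ids) to split without leakage")
            n_inner = max(int(round(1.0 / self.calib_fraction)), 2)
            groups = np.asarray(groups)
            n_inner = min(n_inner, np.unique(groups).size)
            splits = list(GroupKFold(n_splits=n_inner).split(Xm, y, groups))
            if any(np.unique(y[tr]).size < 2 for tr, _ in splits):
                raise ValueError("calibration split left a single-class "
                                 "training partition")
            # inner calibration parts must contain both classes, otherwise
            # the isotonic map is a useless constant; keep usable splits
            usable = [(tr, cal) for tr, cal in splits
                      if np.unique(y[cal]).size == 2]
            if len(usable) >= 2:
                model = CalibratedClassifierCV(base, method="isotonic",
                                               cv=usable)
                model.fit(Xm, y)
            else:
                # degenerate small-sample fallback: in-sample isotonic
                base.fit(Xm, y)
                iso = IsotonicRegression(y_min=0.0, y_max=1.0,
                                         out_of_bounds="clip")
                iso.fit(base.predict_proba(Xm)[:, 1], y)
                model = _InSampleCalibrated(base, iso)
        else:
            model = base
            model.fit(Xm, y)
        self.base_estimator_ = model
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "base_estimator_")
        Xm = _as_frame(X).loc[:, list(self.feature_names_)].to_numpy(dtype=float)
        p = self.base_estimator_.predict_proba(Xm)[:, 1]
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class CompositeRuleClassifier(ClassifierMixin, BaseEstimator):
    """Deterministic composite-rule comparator (no fitting).

    ``predict_proba`` returns hard 0/1 probabilities from the clinical rule
    applied to the observed features, so ranking metrics see only the two
    operating points the rule can produce.
    """

    def __init__(self, thresholds: RuleThresholds | None = None):
        self.thresholds = thresholds

    def _score(self, X) -> np.ndarray:
        t = self.thresholds or RuleThresholds()
        X = _as_frame(X)
        return rule_margin_score(X["hq_dyn"].to_numpy(),
                                 X["lsi_knee_moment"].to_numpy(),
                                 X["cci_early_stance"].to_numpy(), t)

    def fit(self, X, y=None, groups=None):
        self.classes_ = np.array([0, 1])
        self.fitted_ = True
        return self

    def predict_proba(self, X):
        p = (self._score(X) > 0).astype(float)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self._score(X) > 0).astype(int)


class CalibratedRuleClassifier(CompositeRuleClassifier):
    """Isotonic-calibrated continuous rule score.

    The distance-to-threshold score is monotone in imbalance severity;
    isotonic regression fitted on the training trials maps it to a
    probability, giving the rule ranking capacity and calibrated output.
    """

    def fit(self, X, y, groups=None):
        y = np.asarray(y, dtype=int)
        self.calibrator_ = IsotonicRegression(
            y_min=0.0, y_max=1.0, out_of_bounds="clip").fit(self._score(X), y)
        self.classes_ = np.array([0, 1])
        self.fitted_ = True
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "calibrator_")
        p = self.calibrator_.predict(self._score(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def make_grouped_folds(subject_ids, n_folds: int = 5,
                       seed: int | None = 0) -> np.ndarray:
    """Subject-wise fold assignment: one fold id per entry of ``subject_ids``.

    Subjects are shuffled and partitioned into ``n_folds`` near-equal groups;
    all trials of a subject share a fold.
    """
    subject_ids = np.asarray(subject_ids)
    unique = pd.unique(subject_ids)
    if unique.size < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {unique.size}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique.size)
    fold_of_subject = {unique[j]: int(k % n_folds)
                       for k, j in enumerate(order)}
    return np.asarray([fold_of_subject[s] for s in subject_ids], dtype=int)


def fit_predict_oof(features: pd.DataFrame, labels, folds,
                    model: BaseEstimator,
                    subject_ids=None, return_models: bool = False):
    """Out-of-fold calibrated probabilities for every trial.

    For each fold the model is cloned, fitted on the other folds' trials
    (with subject groups), and used to predict the held-out trials.
    Returns an OofPredictions frame: trial_id, subject_id, fold_id, prob,
    label_observed, speed_band.  With ``return_models=True`` also returns
    the fitted per-fold estimators (keyed by fold id).
    """
    labels = np.asarray(labels, dtype=int)
    folds = np.asarray(folds, dtype=int)
    if subject_ids is None:
        subject_ids = features["subject_id"].to_numpy()
    subject_ids = np.asarray(subject_ids)
    prob = np.full(len(labels), np.nan)
    models: dict[int, BaseEstimator] = {}
    for k in np.unique(folds):
        tr = folds != k
        est = clone(model)
        est.fit(features.loc[tr], labels[tr], groups=subject_ids[tr])
        prob[~tr] = est.predict_proba(features.loc[~tr])[:, 1]
        models[int(k)] = est
    out = pd.DataFrame({
        "trial_id": (features["trial_id"].to_numpy()
                     if "trial_id" in features else np.arange(len(labels))),
        "subject_id": subject_ids,
        "fold_id": folds,
        "prob": prob,
        "label_observed": labels,
    })
    if "speed_band" in features:
        out["speed_band"] = features["speed_band"].to_numpy()
    if return_models:
        return out, models
    return out


def predict_rule_configs(features: pd.DataFrame, labels, folds,
                         thresholds: RuleThresholds | None = None
                         ) -> dict[str, pd.DataFrame]:
    """The two rule comparators on the same folds: deterministic + calibrated."""
    return {
        "rule": fit_predict_oof(features, labels, folds,
                                CompositeRuleClassifier(thresholds)),
        "calibrated_rule": fit_predict_oof(features, labels, folds,
                                           CalibratedRuleClassifier(thresholds)),
    }


def run_ablation_suite(table: pd.DataFrame, seed: int = 0, n_folds: int = 5,
                       thresholds: RuleThresholds | None = None,
                       include_logistic: bool = True,
                       label_col: str = "label_observed"
                       ) -> dict[str, pd.DataFrame]:
    """All study configurations on one shared subject-wise fold assignment."""
    labels = table[label_col].to_numpy(dtype=int)
    folds = make_grouped_folds(table["subject_id"].to_numpy(), n_folds, seed)
    suite: dict[str, pd.DataFrame] = {}
    for name, mask in (("full_ml", "full"),
                       ("no_label_ml", "no_label_features"),
                       ("label_only_ml", "label_features_only")):
        model = CalibratedTrialClassifier(family="gbdt", feature_mask=mask,
                                          random_state=seed)
        suite[name] = fit_predict_oof(table, labels, folds, model)
    if include_logistic:
        suite["logistic"] = fit_predict_oof(
            table, labels, folds,
            CalibratedTrialClassifier(family="logistic", feature_mask="full",
                                      random_state=seed))
    suite.update(predict_rule_configs(table, labels, folds, thresholds))
    return suite
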