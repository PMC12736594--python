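"""Model interpretability: permutation importance, partial dependence,
and sampled Shapley attributions.

Permutation importance uses held-out data and the balanced-accuracy drop
(robust to prevalence), normalised to sum to one with negative raw drops
clipped at zero.  Partial dependence is the mean predicted probability over
a background sample with one feature pinned to each grid value.  Shapley
values use Monte-Carlo permutation sampling over the eight features;
contributions plus the base value reproduce the model's prediction up to
Monte-Carlo error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import make_scorer, balanced_accuracy_score


def permutation_importance_report(model, X: pd.DataFrame, y,
                                  metric: str = "balanced_accuracy",
                                  n_repeats: int = 10,
                                  seed: int | None = 0) -> pd.DataFrame:
    """Per-feature mean metric drop over repeated within-column shuffles.

    Returns a frame with columns ``feature``, ``raw_importance``,
    ``normalized_importance`` (clipped at zero, sums to 1) and ``rank``.
    """
    if n_repeats < 5:
        raise ValueError("n_repeats must be at least 5")
    features = list(model.feature_names_)
    scorer = (make_scorer(balanced_accuracy_score)
              if metric == "balanced_accuracy" else metric)
    result = _sk_permutation_importance(
        model, X, np.asarray(y, dtype=int), scoring=scorer,
        n_repeats=n_repeats, random_state=seed)
    # sklearn permutes every column of X; restrict to the model's features
    cols = list(X.columns)
    raw = np.array([result.importances_mean[cols.index(f)] for f in features])
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    norm = clipped / total if total > 0 else np.full_like(clipped, 1.0 / len(clipped))
    out = pd.DataFrame({
        "feature": features,
        "raw_importance": raw,
        "normalized_importance": norm,
    })
    out["rank"] = out["raw_importance"].rank(ascending=False,
                                             method="min").astype(int)
    return out.sort_values("rank", ignore_index=True)


def partial_dependence_curve(model, background: pd.DataFrame, feature: str,
                             grid) -> pd.DataFrame:
    """PD(g) = mean predicted probability with ``feature`` set to ``g``."""
    if len(background) == 0:
        raise ValueError("background sample must be non-empty")
    grid = np.asarray(grid, dtype=float)
    values = []
    work = background.copy()
    for g in grid:
        work[feature] = g
        values.append(float(model.predict_proba(work)[:, 1].mean()))
    return pd.DataFrame({feature: grid, "partial_dependence": values})


def sampled_shapley(model, row: pd.Series | pd.DataFrame,
                    background: pd.DataFrame, n_samples: int = 200,
                    seed: int | None = 0) -> tuple[pd.Series, float]:
    """Monte-Carlo permutation-sampling Shapley attribution for one trial.

    For each sample a background row and a random feature ordering are
    drawn; features are switched from the background value to the explained
    row's value one at a time and the prediction increments are credited to
    the switched feature.  Returns (per-feature contributions, base value);
    ``base + sum(contributions)`` equals the model's prediction for the row
    up to Monte-Carlo error.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    if isinstance(row, pd.DataFrame):
        row = row.iloc[0]
    features = list(model.feature_names_)
    rng = np.random.default_rng(seed)
    bg = background[features].to_numpy(dtype=float)
    x = row[features].to_numpy(dtype=float)
    n_feat = len(features)

    # build every intermediate coalition, then predict in one batch
    stack = np.empty((n_samples * (n_feat + 1), n_feat))
    orders = np.empty((n_samples, n_feat), dtype=int)
    for s in range(n_samples):
        base_row = bg[rng.integers(len(bg))].copy()
        order = rng.permutation(n_feat)
        orders[s] = order
        cur = base_row.copy()
        stack[s * (n_feat + 1)] = cur
        for k, j in enumerate(order):
            cur[j] = x[j]
            stack[s * (n_feat + 1) + k + 1] = cur
    preds = model.predict_proba(
        pd.DataFrame(stack, columns=features))[:, 1]
    preds = preds.reshape(n_samples, n_feat + 1)

    contrib = np.zeros(n_feat)
    for s in range(n_samples):
        inc = np.diff(preds[s])
        contrib[orders[s]] += inc
    contrib /= n_samples
    base_value = float(preds[:, 0].mean())
    return pd.Series(contrib, index=features), base_value
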