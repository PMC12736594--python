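"""Composite-rule labeling, stochastic flips, and the continuous rule score.

The clinical rule is a disjunction of three criteria: H:Qdyn outside
(0.60, 1.20), |knee-moment LSI| above 12%, or early-stance CCI above 0.58
(strict inequalities).  The rule-margin score is the per-criterion signed
distance to threshold, normalised by approximate trial-level SDs and
combined with a max, so it is positive exactly on the imbalanced region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RuleThresholds


def apply_composite_rule(hq, lsi, cci,
                         thresholds: RuleThresholds | None = None):
    """Binary imbalance label; vectorised over array-like inputs."""
    t = thresholds or RuleThresholds()
    hq = np.asarray(hq, dtype=float)
    lsi = np.asarray(lsi, dtype=float)
    cci = np.asarray(cci, dtype=float)
    out = ((hq < t.hq_low) | (hq > t.hq_high)
           | (np.abs(lsi) > t.lsi_abs) | (cci > t.cci_max))
    if out.ndim == 0:
        return bool(out)
    return out.astype(int)


def rule_margin_score(hq, lsi, cci,
                      thresholds: RuleThresholds | None = None):
    """Continuous distance-to-threshold score, positive iff rule-imbalanced."""
    t = thresholds or RuleThresholds()
    hq = np.asarray(hq, dtype=float)
    lsi = np.asarray(lsi, dtype=float)
    cci = np.asarray(cci, dtype=float)
    m_hq = np.maximum(t.hq_low - hq, hq - t.hq_high) / t.margin_scale_hq
    m_lsi = (np.abs(lsi) - t.lsi_abs) / t.margin_scale_lsi
    m_cci = (cci - t.cci_max) / t.margin_scale_cci
    score = np.maximum(np.maximum(m_hq, m_lsi), m_cci)
    return float(score) if score.ndim == 0 else score


def flip_labels(labels, flip_rate: float, seed: int | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Invert each label independently with probability ``flip_rate``.

    Flips are uniform across all strata (speed bands, classes).  Returns the
    flipped labels and the boolean flip indicator.
    """
    if not 0.0 <= flip_rate <= 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5]")
    labels = np.asarray(labels, dtype=int)
    if rng is None:
        rng = np.random.default_rng(seed)
    flips = rng.random(labels.shape) < flip_rate
    return np.where(flips, 1 - labels, labels), flips


def label_feature_table(table: pd.DataFrame, flip_rate: float = 0.05,
                        thresholds: RuleThresholds | None = None,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        source: str = "latent") -> pd.DataFrame:
    """Append label_latent, label_observed, flip_flag, rule_score columns.

    ``source`` selects which feature columns drive the latent label: the
    noise-free latent values (``"latent"``, the generator's convention) or
    the observed columns for tables without a latent layer.  The rule score
    is always computed from the observed (noisy) features, mirroring what a
    deployed rule would see.
    """
    t = thresholds or RuleThresholds()
    table = table.copy()
    prefix = "latent_" if source == "latent" else ""
    lat = [table[f"{prefix}{c}"].to_numpy()
           for c in ("hq_dyn", "lsi_knee_moment", "cci_early_stance")]
    table["label_latent"] = apply_composite_rule(*lat, t)
    obs = [table[c].to_numpy()
           for c in ("hq_dyn", "lsi_knee_moment", "cci_early_stance")]
    table["rule_score"] = rule_margin_score(*obs, t)
    flipped, flags = flip_labels(table["label_latent"].to_numpy(),
                                 flip_rate, seed=seed, rng=rng)
    table["label_observed"] = flipped
    table["flip_flag"] = flags.astype(int)
    return table
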