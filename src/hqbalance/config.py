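"""Configuration models for the synthetic cohort and the analysis pipeline.

All knobs of the data-generating process live in :class:`SimulationConfig` so
that a single JSON document fully determines a study run.  The defaults encode
the reference study conditions: 160 virtual subjects, 573 running trials over
three speed bands, a five-archetype mixture of muscular-balance phenotypes,
composite-rule labels with 5% stochastic flips, and an IMU-like measurement
layer (additive waveform noise plus per-channel gain error).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, field_validator, model_validator

ARCHETYPES = (
    "balanced",
    "quad_dominant",
    "ham_dominant",
    "asymmetric",
    "co_contractor",
)

#: The seven latent (label-generating) trial features, in canonical order.
LATENT_FEATURES = (
    "hq_dyn",
    "lsi_knee_moment",
    "cci_early_stance",
    "lsi_grf",
    "lsi_stance_time",
    "ttp_kfm",
    "stride_cv",
)

#: Observed model features: the seven biomechanical features plus speed.
FEATURE_COLUMNS = LATENT_FEATURES + ("speed",)


class TruncNormalSpec(BaseModel):
    """Location/scale/truncation of a truncated-normal trait distribution."""

    loc: float
    scale: float = Field(ge=0.0)
    low: float
    high: float

    @model_validator(mode="after")
    def _check_bounds(self) -> "TruncNormalSpec":
        if not self.low < self.high:
            raise ValueError("truncation bounds must satisfy low < high")
        return self


# Baseline trait distributions shared by every archetype; each archetype then
# overrides the trait(s) that define its phenotype.  LSIs are percent, H:Qdyn
# and CCI dimensionless, TTP-KFM percent of stance, stride CV percent.
_BALANCED_TRAITS: dict[str, TruncNormalSpec] = {
    "hq_dyn": TruncNormalSpec(loc=0.92, scale=0.10, low=0.65, high=1.15),
    "lsi_knee_moment": TruncNormalSpec(loc=0.0, scale=4.4, low=-30.0, high=30.0),
    "cci_early_stance": TruncNormalSpec(loc=0.42, scale=0.07, low=0.20, high=0.56),
    "ttp_kfm": TruncNormalSpec(loc=55.0, scale=2.0, low=45.0, high=70.0),
    "stride_cv": TruncNormalSpec(loc=2.4, scale=0.7, low=1.0, high=5.0),
}

_ARCHETYPE_OVERRIDES: dict[str, dict[str, TruncNormalSpec]] = {
    "balanced": {},
    "quad_dominant": {
        "hq_dyn": TruncNormalSpec(loc=0.52, scale=0.05, low=0.40, high=0.565),
        "cci_early_stance": TruncNormalSpec(loc=0.45, scale=0.05, low=0.30, high=0.58),
    },
    "ham_dominant": {
        "hq_dyn": TruncNormalSpec(loc=1.33, scale=0.07, low=1.28, high=1.56),
        "cci_early_stance": TruncNormalSpec(loc=0.44, scale=0.05, low=0.30, high=0.58),
    },
    # magnitude of the signed knee-moment LSI; the sign is drawn separately
    "asymmetric": {
        "lsi_knee_moment": TruncNormalSpec(loc=17.0, scale=2.5, low=15.0, high=27.0),
        "cci_early_stance": TruncNormalSpec(loc=0.46, scale=0.05, low=0.28, high=0.58),
    },
    "co_contractor": {
        "cci_early_stance": TruncNormalSpec(loc=0.72, scale=0.05, low=0.66, high=0.90),
    },
}

#: Imbalanced archetypes express noisier, less well-timed gait: elevated
#: stride-to-stride variability and a shifted (early or late) flexor peak.
_IMBALANCED_STRIDE_CV = TruncNormalSpec(loc=3.0, scale=0.8, low=1.5, high=7.0)
_IMBALANCED_TTP_SHIFT = 4.5  # percent of stance, random sign per subject


class ArchetypeTraits(BaseModel):
    """Per-archetype trait distributions (baseline plus overrides)."""

    overrides: dict[str, dict[str, TruncNormalSpec]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in _ARCHETYPE_OVERRIDES.items()}
    )
    baseline: dict[str, TruncNormalSpec] = Field(
        default_factory=lambda: dict(_BALANCED_TRAITS)
    )
    imbalanced_stride_cv: TruncNormalSpec = Field(
        default_factory=lambda: _IMBALANCED_STRIDE_CV.model_copy()
    )
    imbalanced_ttp_shift: float = _IMBALANCED_TTP_SHIFT
    # secondary asymmetries track the knee-moment LSI with attenuation + noise
    grf_lsi_slope: float = 0.5
    grf_lsi_noise_sd: float = Field(default=1.5, ge=0.0)
    stance_lsi_slope: float = 0.3
    stance_lsi_noise_sd: float = Field(default=1.2, ge=0.0)

    def distribution(self, archetype: str, trait: str) -> TruncNormalSpec:
        over = self.overrides.get(archetype, {})
        if trait in over:
            return over[trait]
        return self.baseline[trait]


class SimulationConfig(BaseModel):
    """Full specification of one synthetic running study."""

    n_subjects: int = Field(default=160, ge=1)
    n_trials_total: int = Field(default=573, ge=1)
    speed_bands: list[float] = Field(default_factory=lambda: [2.8, 3.4, 4.2])
    archetype_weights: list[float] = Field(
        default_factory=lambda: [0.50, 0.19, 0.10, 0.16, 0.05]
    )
    traits: ArchetypeTraits = Field(default_factory=ArchetypeTraits)

    # trial-to-trial latent variability around the subject trait mean
    trial_noise_sd: dict[str, float] = Field(
        default_factory=lambda: {
            "hq_dyn": 0.02,
            "lsi_knee_moment": 1.5,
            "cci_early_stance": 0.015,
            "lsi_grf": 0.6,
            "lsi_stance_time": 0.45,
            "ttp_kfm": 1.5,
            "stride_cv": 0.4,
        }
    )
    # mild amplification of asymmetry/variability expression at higher speeds
    speed_lsi_amplification: list[float] = Field(
        default_factory=lambda: [1.0, 1.02, 1.04]
    )
    speed_stride_cv_shift: list[float] = Field(default_factory=lambda: [0.0, 0.15, 0.45])
    # archetype-specific variability/timing signatures are diluted at speed:
    # baseline variability rises for everyone, masking the imbalance signal
    speed_signature_scale: list[float] = Field(default_factory=lambda: [1.15, 1.0, 0.8])
    # secondary load/timing asymmetries (GRF, stance time) are expressed
    # most cleanly at low speed; impact dynamics compress them when fast
    speed_aux_scale: list[float] = Field(default_factory=lambda: [1.2, 1.0, 0.65])

    # measurement layer: additive white noise (fraction of per-signal peak)
    # and per-trial multiplicative gain errors emulating sensor calibration
    # drift; both scale with speed (soft-tissue artifact grows with impact
    # intensity).  Gains are drawn per limb: one common gain for the two
    # moment channels (so inter-limb symmetry is noisy while the
    # within-limb flexor/extensor ratio is protected), an extra
    # flexor-specific gain, a GRF gain, and one gain per activation channel.
    measurement_noise_sd: float = Field(default=0.025, ge=0.0)
    channel_gain_sd: dict[str, float] = Field(
        default_factory=lambda: {
            "moment": 0.028,
            "flexor": 0.012,
            "grf": 0.012,
            "activation": 0.05,
        }
    )
    speed_measurement_scale: list[float] = Field(
        default_factory=lambda: [0.65, 1.0, 1.5]
    )
    # deterministic read biases: sensor-derived inter-limb moment asymmetry
    # is compressed at low and exaggerated at high speed (soft-tissue
    # artifact), and the hamstrings channel reads slightly hot when fast
    speed_lsi_read_bias: list[float] = Field(
        default_factory=lambda: [0.66, 1.0, 1.37]
    )
    speed_ham_gain_bias: list[float] = Field(
        default_factory=lambda: [0.96, 1.0, 1.05]
    )

    flip_rate: float = Field(default=0.05, ge=0.0, le=0.5)
    n_strides_per_trial: int = Field(default=10, ge=2)
    fs: float = Field(default=200.0, gt=0.0)
    stance_durations_s: list[float] = Field(default_factory=lambda: [0.26, 0.22, 0.19])
    stance_jitter: float = Field(default=0.05, ge=0.0, lt=0.5)
    filter_cutoff_hz: float = Field(default=6.0, gt=0.0)
    filter_order: int = Field(default=4, ge=1)
    seed: int = 0

    @field_validator("speed_bands")
    @classmethod
    def _bands_increasing(cls, v: list[float]) -> list[float]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("speed_bands must be strictly increasing")
        return v

    @field_validator("trial_noise_sd")
    @classmethod
    def _noise_nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        if any(s < 0 for s in v.values()):
            raise ValueError("trial noise SDs must be >= 0")
        return v

    @field_validator("channel_gain_sd", mode="before")
    @classmethod
    def _gain_sd(cls, v):
        if isinstance(v, (int, float)):  # scalar shorthand: same SD everywhere
            v = {k: float(v) for k in ("moment", "flexor", "grf", "activation")}
        if any(s < 0 for s in v.values()):
            raise ValueError("gain SDs must be >= 0")
        return v

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if len(self.archetype_weights) != len(ARCHETYPES):
            raise ValueError(
                f"archetype_weights must have {len(ARCHETYPES)} entries"
            )
        if any(w < 0 for w in self.archetype_weights):
            raise ValueError("archetype_weights must be non-negative")
        if abs(sum(self.archetype_weights) - 1.0) > 1e-9:
            raise ValueError("archetype_weights must sum to 1")
        if self.n_trials_total < self.n_subjects:
            raise ValueError("n_trials_total must be >= n_subjects")
        if len(self.stance_durations_s) != len(self.speed_bands):
            raise ValueError("stance_durations_s must match speed_bands")
        for name in ("speed_lsi_amplification", "speed_stride_cv_shift",
                     "speed_measurement_scale", "speed_signature_scale",
                     "speed_aux_scale", "speed_lsi_read_bias",
                     "speed_ham_gain_bias"):
            if len(getattr(self, name)) != len(self.speed_bands):
                raise ValueError(f"{name} must match speed_bands")
        if any(not 0.1 <= d <= 0.4 for d in self.stance_durations_s):
            raise ValueError("stance durations must lie in [0.1, 0.4] s")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


class RuleThresholds(BaseModel):
    """Clinical cut-offs of the composite imbalance rule.

    A trial is imbalanced when H:Qdyn < ``hq_low`` or > ``hq_high``, or
    |knee-moment LSI| > ``lsi_abs``, or CCI > ``cci_max`` (strict
    inequalities; boundary equality counts as balanced).  The margin scales
    normalise per-criterion distances to threshold onto comparable units
    (approximate trial-level SDs) before the disjunctive max.
    """

    hq_low: float = 0.60
    hq_high: float = 1.20
    lsi_abs: float = Field(default=12.0, gt=0.0)
    cci_max: float = 0.58
    margin_scale_hq: float = Field(default=0.10, gt=0.0)
    margin_scale_lsi: float = Field(default=4.0, gt=0.0)
    margin_scale_cci: float = Field(default=0.06, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "RuleThresholds":
        if not self.hq_low < self.hq_high:
            raise ValueError("hq_low must be < hq_high")
        if not 0.0 < self.cci_max < 1.0:
            raise ValueError("cci_max must lie in (0, 1)")
        return self


class ModelConfig(BaseModel):
    """One classifier configuration of the ablation ladder."""

    family: Literal["gbdt", "logistic", "rule", "calibrated_rule"] = "gbdt"
    feature_mask: Literal["full", "no_label_features", "label_features_only"] = "full"
    calibration: Literal["isotonic", "none"] = "isotonic"
    n_estimators: int = Field(default=400, ge=1)
    max_depth: int = Field(default=2, ge=1)
    min_samples_leaf: int = Field(default=20, ge=1)
    learning_rate: float = Field(default=0.05, gt=0.0)
    subsample: float = Field(default=0.9, gt=0.0, le=1.0)
    logistic_c: float = Field(default=1000.0, gt=0.0)
    calib_fraction: float = Field(default=0.2, gt=0.0, lt=1.0)
    n_folds: int = Field(default=5, ge=2)
    classification_threshold: float = Field(default=0.5, gt=0.0, lt=1.0)
    seed: int = 0
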