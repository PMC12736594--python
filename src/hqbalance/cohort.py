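"""Virtual cohort sampling: subject archetypes, trait means, and trial plans.

A subject belongs to one of five muscular-balance archetypes (balanced,
quad-dominant, ham-dominant, asymmetric, co-contractor).  Trait means are
drawn from archetype-specific truncated normal distributions; per-trial
latent feature values add trial-to-trial noise and a mild speed effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import ARCHETYPES, LATENT_FEATURES, SimulationConfig, TruncNormalSpec

IMBALANCED_ARCHETYPES = frozenset(
    {"quad_dominant", "ham_dominant", "asymmetric", "co_contractor"}
)


@dataclass
class SubjectProfile:
    """Latent archetype and trait means for one virtual subject."""

    subject_id: str
    archetype: str
    trait_means: dict[str, float] = field(default_factory=dict)
    dominant_side: str = "left"

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.trait_means:
            missing = set(LATENT_FEATURES) - set(self.trait_means)
            if missing:
                raise ValueError(f"trait_means missing {sorted(missing)}")
            if self.trait_means["hq_dyn"] <= 0:
                raise ValueError("latent H:Qdyn mean must be positive")
            if not 0.0 < self.trait_means["cci_early_stance"] < 1.0:
                raise ValueError("latent CCI mean must lie in (0, 1)")


def _draw_truncnorm(spec: TruncNormalSpec, rng: np.random.Generator,
                    size: int | None = None) -> float | np.ndarray:
    if spec.scale == 0:
        return spec.loc if size is None else np.full(size, spec.loc)
    a = (spec.low - spec.loc) / spec.scale
    b = (spec.high - spec.loc) / spec.scale
    return stats.truncnorm.rvs(a, b, loc=spec.loc, scale=spec.scale,
                               size=size, random_state=rng)


def sample_cohort(config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> list[SubjectProfile]:
    """Draw ``config.n_subjects`` subject profiles from the archetype mixture."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    weights = np.asarray(config.archetype_weights, dtype=float)
    traits = config.traits
    cohort: list[SubjectProfile] = []
    arch_idx = rng.choice(len(ARCHETYPES), size=config.n_subjects, p=weights)
    for i, ai in enumerate(arch_idx):
        archetype = ARCHETYPES[ai]
        means: dict[str, float] = {}
        for trait in ("hq_dyn", "lsi_knee_moment", "cci_early_stance",
                      "ttp_kfm", "stride_cv"):
            means[trait] = float(_draw_truncnorm(
                traits.distribution(archetype, trait), rng))
        if archetype == "asymmetric" and rng.random() < 0.5:
            means["lsi_knee_moment"] = -means["lsi_knee_moment"]
        if archetype in IMBALANCED_ARCHETYPES:
            means["stride_cv"] = float(_draw_truncnorm(
                traits.imbalanced_stride_cv, rng))
            shift = traits.imbalanced_ttp_shift * (1 if rng.random() < 0.5 else -1)
            means["ttp_kfm"] = float(np.clip(
                means["ttp_kfm"] + shift,
                traits.baseline["ttp_kfm"].low, traits.baseline["ttp_kfm"].high))
        # secondary load asymmetries track the knee-moment LSI with
        # attenuation plus independent subject-level noise
        means["lsi_grf"] = (traits.grf_lsi_slope * means["lsi_knee_moment"]
                            + rng.normal(0.0, traits.grf_lsi_noise_sd))
        means["lsi_stance_time"] = (
            traits.stance_lsi_slope * means["lsi_knee_moment"]
            + rng.normal(0.0, traits.stance_lsi_noise_sd))
        cohort.append(SubjectProfile(
            subject_id=f"S{i:04d}",
            archetype=archetype,
            trait_means=means,
            dominant_side="left" if means["lsi_knee_moment"] >= 0 else "right",
        ))
    return cohort


def plan_trials(cohort: list[SubjectProfile], config: SimulationConfig,
                rng: np.random.Generator | None = None) -> list[tuple[str, int]]:
    """Assign each subject 3 or 4 trials so totals match, spread over bands.

    Bands are assigned round-robin within each subject (every subject visits
    all three speed bands at least once) and the overall trial order is then
    shuffled.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    n_sub = len(cohort)
    n_bands = len(config.speed_bands)
    total = config.n_trials_total
    if not n_sub * 3 <= total <= n_sub * 4:
        raise ValueError(
            f"n_trials_total={total} must lie in [3*{n_sub}, 4*{n_sub}] "
            "for a 3-or-4-trials-per-subject plan")
    extra = total - 3 * n_sub
    four_trial_ids = set(rng.choice(n_sub, size=extra, replace=False).tolist())
    plan: list[tuple[str, int]] = []
    for i, profile in enumerate(cohort):
        n_trials = 4 if i in four_trial_ids else 3
        bands = rng.permutation(n_bands)
        for t in range(n_trials):
            plan.append((profile.subject_id, int(bands[t % n_bands])))
    order = rng.permutation(len(plan))
    return [plan[k] for k in order]


def sample_trial_latents(profile: SubjectProfile, speed_band: int,
                         config: SimulationConfig,
                         rng: np.random.Generator) -> dict[str, float]:
    """Target latent feature values for one trial.

    Subject trait mean + independent trial noise, with asymmetry expression
    mildly amplified and stride variability elevated at faster speeds.  These
    are the *targets* the waveform synthesiser realises; labels are applied
    to the realised values.
    """
    noise = config.trial_noise_sd
    amp = config.speed_lsi_amplification[speed_band]
    cv_shift = config.speed_stride_cv_shift[speed_band]
    sig = config.speed_signature_scale[speed_band]
    base = config.traits.baseline
    latent: dict[str, float] = {}
    for feat in LATENT_FEATURES:
        latent[feat] = profile.trait_means[feat] + rng.normal(0.0, noise.get(feat, 0.0))
    for feat in ("lsi_knee_moment", "lsi_grf", "lsi_stance_time"):
        latent[feat] *= amp
    aux = config.speed_aux_scale[speed_band]
    for feat in ("lsi_grf", "lsi_stance_time"):
        latent[feat] *= aux
    # variability/timing signatures are expressed relative to the cohort
    # baseline and fade at higher speeds
    for feat in ("stride_cv", "ttp_kfm"):
        latent[feat] = (base[feat].loc
                        + (latent[feat] - base[feat].loc) * sig)
    latent["stride_cv"] += cv_shift
    # keep values inside physically meaningful ranges
    latent["hq_dyn"] = float(np.clip(latent["hq_dyn"], 0.2, 2.5))
    latent["cci_early_stance"] = float(np.clip(latent["cci_early_stance"], 0.02, 0.95))
    latent["ttp_kfm"] = float(np.clip(latent["ttp_kfm"], 42.0, 68.0))
    latent["stride_cv"] = float(np.clip(latent["stride_cv"], 0.2, 9.0))
    for feat in ("lsi_knee_moment", "lsi_grf", "lsi_stance_time"):
        latent[feat] = float(np.clip(latent[feat], -40.0, 40.0))
    return latent
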