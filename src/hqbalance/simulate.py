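"""End-to-end synthetic dataset generation.

``generate_dataset`` runs cohort sampling, trial planning, waveform
synthesis, latent-feature realisation, measurement noise, feature
extraction, and labeling, returning the trials, the cohort, and the
analysis-ready feature table.  Everything is reproducible from the config
seed; per-stage generators are derived from it with fixed stream tags.

Two conventions matter downstream.  First, a trial's *latent* features are
the values realised by the noise-free constructed waveforms after the same
filtering and segmentation the extractor applies: the construction targets
are hit to within discretisation, and storing the realised values makes the
latent layer exactly consistent with what a noise-free measurement would
observe.  Labels are applied to these latent values.  Second, *observed*
features are extracted from the waveforms after the measurement layer, so
the observed-vs-latent gap is entirely attributable to measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (SubjectProfile, plan_trials, sample_cohort,
                     sample_trial_latents)
from .config import LATENT_FEATURES, RuleThresholds, SimulationConfig
from .features import extract_waveform_features
from .labeling import label_feature_table
from .waveforms import TrialRecord, apply_measurement_noise, synthesize_trial_waveforms

_STREAMS = {"cohort": 11, "plan": 13, "latent": 17, "waveform": 19, "flip": 23}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _STREAMS[stream]]))


@dataclass
class DatasetBundle:
    cohort: list[SubjectProfile]
    trials: list[TrialRecord]
    table: pd.DataFrame


def generate_dataset(config: SimulationConfig | None = None,
                     thresholds: RuleThresholds | None = None
                     ) -> DatasetBundle:
    """Generate the full cohort, trials with waveforms, and feature table."""
    config = config or SimulationConfig()
    thresholds = thresholds or RuleThresholds()
    cohort = sample_cohort(config, _rng(config, "cohort"))
    profiles = {p.subject_id: p for p in cohort}
    plan = plan_trials(cohort, config, _rng(config, "plan"))
    rng_lat = _rng(config, "latent")
    rng_wav = _rng(config, "waveform")

    trials: list[TrialRecord] = []
    rows: list[dict] = []
    for i, (subject_id, band) in enumerate(plan):
        profile = profiles[subject_id]
        target = sample_trial_latents(profile, band, config, rng_lat)
        record = synthesize_trial_waveforms(
            profile, config.speed_bands[band], target, config, rng_wav,
            speed_band=band, trial_id=f"T{i:04d}")
        # realised latent features: noise-free waveforms through the extractor
        record.latent_features = extract_waveform_features(record, config)
        apply_measurement_noise(record, config, rng_wav)
        observed = extract_waveform_features(record, config)
        row = {"trial_id": record.trial_id, "subject_id": subject_id,
               "archetype": profile.archetype, "speed_band": band,
               "speed": record.speed}
        row.update(observed)
        row.update({f"latent_{k}": v for k, v in record.latent_features.items()})
        rows.append(row)
        trials.append(record)

    table = pd.DataFrame(rows)
    table = label_feature_table(table, flip_rate=config.flip_rate,
                                thresholds=thresholds,
                                rng=_rng(config, "flip"), source="latent")
    return DatasetBundle(cohort=cohort, trials=trials, table=table)


def simulate_latent_table(config: SimulationConfig | None = None,
                          thresholds: RuleThresholds | None = None
                          ) -> pd.DataFrame:
    """Feature table from the latent layer only (no waveform synthesis).

    The latent targets stand in for both latent and observed features; this
    is the measurement-free limit of the generator and is used where
    waveform-level effects are deliberately absent (e.g. analytic flip-noise
    experiments).
    """
    config = config or SimulationConfig()
    thresholds = thresholds or RuleThresholds()
    cohort = sample_cohort(config, _rng(config, "cohort"))
    profiles = {p.subject_id: p for p in cohort}
    plan = plan_trials(cohort, config, _rng(config, "plan"))
    rng_lat = _rng(config, "latent")
    rows = []
    for i, (subject_id, band) in enumerate(plan):
        profile = profiles[subject_id]
        latent = sample_trial_latents(profile, band, config, rng_lat)
        row = {"trial_id": f"T{i:04d}", "subject_id": subject_id,
               "archetype": profile.archetype, "speed_band": band,
               "speed": config.speed_bands[band]}
        row.update(latent)
        row.update({f"latent_{k}": latent[k] for k in LATENT_FEATURES})
        rows.append(row)
    table = pd.DataFrame(rows)
    return label_feature_table(table, flip_rate=config.flip_rate,
                               thresholds=thresholds,
                               rng=_rng(config, "flip"), source="latent")
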