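"""Stance-phase waveform synthesis.

Waveforms are phenomenological: raised-cosine bumps for joint moments, a
double-peak vertical GRF, and Gaussian activation bursts.  Only their
integral/peak/timing functionals matter downstream, and each stride is
constructed so that those functionals realise the trial's latent feature
targets exactly (in discrete trapezoidal quadrature, before filtering and
measurement noise):

* the stance integral ratio of |flexor| to |extensor| moment equals H:Qdyn;
* left/right amplitude scaling realises the signed LSIs
  (``L = base*(1+lsi/200)``, ``R = base*(1-lsi/200)`` gives
  ``100*(L-R)/mean(L,R) = lsi`` identically);
* the hamstrings burst is proportional to the quadriceps burst over early
  stance with factor ``alpha = cci/(2-cci)``, so the Falconer-Winter overlap
  equals CCI;
* the flexor-moment peak sits at TTP-KFM percent of stance;
* per-stride multiplicative amplitude jitter with unit mean and sample CV
  equal to the stride-CV target realises the variability feature.

The measurement layer then applies a per-trial, per-channel multiplicative
gain error and additive white Gaussian noise scaled to each signal's peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import SubjectProfile
from .config import SimulationConfig

SIGNALS = ("knee_ext_moment", "knee_flex_moment", "grf", "act_ham", "act_quad")
LIMBS = ("left", "right")

#: Nominal signal scales: peak knee extensor moment (N·m/kg), peak vertical
#: GRF (body weights), peak quadriceps activation (normalised).
EXT_MOMENT_PEAK = 2.2
GRF_PEAK = 2.5
ACT_PEAK = 0.8
HAM_LATE_PEAK = 0.4

_MIN_SAMPLES = 24


class GenerationError(ValueError):
    """Latent values outside physically realisable ranges."""


@dataclass
class TrialRecord:
    """One trial: per-limb stance waveforms plus latent features and metadata.

    ``waveforms[signal][limb]`` is a list of 1-D arrays, one per stride
    (stride lengths may differ); ``stance_durations[limb]`` holds per-stride
    stance times in seconds.
    """

    trial_id: str
    subject_id: str
    speed_band: int
    speed: float
    latent_features: dict[str, float] = field(default_factory=dict)
    waveforms: dict[str, dict[str, list[np.ndarray]]] = field(default_factory=dict)
    stance_durations: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_strides(self) -> int:
        return len(next(iter(self.waveforms.values()))["left"])


def raised_cosine(x: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump on [center-width/2, center+width/2], peak 1."""
    lo = center - width / 2.0
    inside = (x >= lo) & (x <= center + width / 2.0)
    out = np.zeros_like(x, dtype=float)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (x[inside] - lo) / width))
    return out


def _gauss(x: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sd) ** 2)


def synthesize_stride(n: int, hq: float, ttp_pct: float, cci: float,
                      ext_peak: float = EXT_MOMENT_PEAK,
                      grf_peak: float = GRF_PEAK) -> dict[str, np.ndarray]:
    """Construct the five stance signals for one stride of ``n`` samples.

    The flexor amplitude is solved so that the trapezoidal integral ratio
    |flexor|/|extensor| equals ``hq`` exactly on the discrete grid.
    """
    if n < 4:
        raise GenerationError(f"stride too short ({n} samples)")
    if hq <= 0:
        raise GenerationError(f"H:Qdyn must be positive, got {hq}")
    if not 0.0 < cci < 1.0:
        raise GenerationError(f"CCI must lie in (0, 1), got {cci}")
    if not 30.0 <= ttp_pct <= 70.0:
        raise GenerationError(f"TTP-KFM {ttp_pct} outside realisable [30, 70]")
    x = np.linspace(0.0, 100.0, n)
    ext = ext_peak * raised_cosine(x, 40.0, 60.0)
    flex_unit = raised_cosine(x, ttp_pct, 60.0)
    flex = flex_unit * (hq * np.trapezoid(np.abs(ext))
                        / np.trapezoid(np.abs(flex_unit)))
    grf = grf_peak * (raised_cosine(x, 25.0, 50.0) + raised_cosine(x, 75.0, 50.0))
    act_q = ACT_PEAK * _gauss(x, 25.0, 12.0)
    alpha = cci / (2.0 - cci)
    act_h = alpha * act_q + HAM_LATE_PEAK * _gauss(x, 75.0, 10.0)
    return {"knee_ext_moment": ext, "knee_flex_moment": flex, "grf": grf,
            "act_ham": act_h, "act_quad": act_q}


def _stride_jitter(cv_pct: float, n_strides: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Multiplicative factors with mean 1 and sample CV (ddof=1) = cv_pct."""
    if cv_pct <= 0 or n_strides < 2:
        return np.ones(n_strides)
    z = rng.standard_normal(n_strides)
    sd = z.std(ddof=1)
    if sd < 1e-12:
        return np.ones(n_strides)
    m = 1.0 + (cv_pct / 100.0) * (z - z.mean()) / sd
    if np.any(m <= 0.05):  # pathological draw at very large CV; resample
        return _stride_jitter(cv_pct, n_strides, rng)
    return m


def synthesize_trial_waveforms(profile: SubjectProfile, speed: float,
                               latent: dict[str, float],
                               config: SimulationConfig,
                               rng: np.random.Generator,
                               speed_band: int | None = None,
                               trial_id: str = "T0000") -> TrialRecord:
    """Noise-free waveforms realising the latent feature targets."""
    bands = np.asarray(config.speed_bands)
    if speed_band is None:
        speed_band = int(np.argmin(np.abs(bands - speed)))
    for key in ("hq_dyn", "lsi_knee_moment", "cci_early_stance", "lsi_grf",
                "lsi_stance_time", "ttp_kfm", "stride_cv"):
        if not np.isfinite(latent[key]):
            raise GenerationError(f"latent {key} is not finite")
    if latent["hq_dyn"] <= 0:
        raise GenerationError("latent H:Qdyn must be positive")
    if not 0.0 < latent["cci_early_stance"] < 1.0:
        raise GenerationError("latent CCI must lie in (0, 1)")

    n_strides = config.n_strides_per_trial
    base_dur = config.stance_durations_s[speed_band]
    dur_jit = 1.0 + rng.uniform(-config.stance_jitter, config.stance_jitter,
                                size=n_strides)
    jitter = _stride_jitter(latent["stride_cv"], n_strides, rng)

    limb_factor = {
        "moment": {"left": 1.0 + latent["lsi_knee_moment"] / 200.0,
                   "right": 1.0 - latent["lsi_knee_moment"] / 200.0},
        "grf": {"left": 1.0 + latent["lsi_grf"] / 200.0,
                "right": 1.0 - latent["lsi_grf"] / 200.0},
        "dur": {"left": 1.0 + latent["lsi_stance_time"] / 200.0,
                "right": 1.0 - latent["lsi_stance_time"] / 200.0},
    }
    for group, sides in limb_factor.items():
        if any(v <= 0 for v in sides.values()):
            raise GenerationError(f"LSI magnitude too large for {group} scaling")

    waveforms: dict[str, dict[str, list[np.ndarray]]] = {
        sig: {limb: [] for limb in LIMBS} for sig in SIGNALS}
    durations: dict[str, list[float]] = {limb: [] for limb in LIMBS}
    for limb in LIMBS:
        for s in range(n_strides):
            dur = base_dur * dur_jit[s] * limb_factor["dur"][limb]
            n = max(int(round(dur * config.fs)) + 1, _MIN_SAMPLES)
            stride = synthesize_stride(
                n, latent["hq_dyn"], latent["ttp_kfm"],
                latent["cci_early_stance"],
                ext_peak=EXT_MOMENT_PEAK * limb_factor["moment"][limb] * jitter[s],
                grf_peak=GRF_PEAK * limb_factor["grf"][limb])
            for sig in SIGNALS:
                waveforms[sig][limb].append(stride[sig])
            durations[limb].append((n - 1) / config.fs)

    return TrialRecord(
        trial_id=trial_id, subject_id=profile.subject_id,
        speed_band=speed_band, speed=float(speed),
        latent_features=dict(latent), waveforms=waveforms,
        stance_durations={limb: np.asarray(d) for limb, d in durations.items()},
    )


def apply_measurement_noise(record: TrialRecord, config: SimulationConfig,
                            rng: np.random.Generator) -> TrialRecord:
    """Add the IMU-like measurement layer in place and return the record.

    Per limb and trial, multiplicative gain errors (sensor calibration
    drift): one gain shared by both knee-moment channels (so the
    within-limb flexor/extensor ratio is preserved while inter-limb
    symmetry is perturbed), an extra flexor-specific gain, a GRF gain, and
    one gain per activation channel.  Then additive white Gaussian noise
    with SD ``measurement_noise_sd`` times the channel's peak amplitude.
    All SDs scale with the speed band.  GRF is clipped at zero, activations
    to [0, 1.2].
    """
    scale = config.speed_measurement_scale[record.speed_band]
    gsd = {k: v * scale for k, v in config.channel_gain_sd.items()}
    add_sd = config.measurement_noise_sd * scale
    # deterministic speed-dependent read biases: the sensor-derived
    # inter-limb moment difference is scaled by gamma (soft-tissue
    # artifact), and the hamstrings activation channel by a band factor
    gamma = config.speed_lsi_read_bias[record.speed_band]
    lsi = record.latent_features.get("lsi_knee_moment", 0.0)
    bias = {"left": 1.0 + (gamma - 1.0) * lsi / 200.0,
            "right": 1.0 - (gamma - 1.0) * lsi / 200.0}
    ham_bias = config.speed_ham_gain_bias[record.speed_band]

    def _gain(sd: float) -> float:
        return rng.normal(1.0, sd) if sd > 0 else 1.0

    gains: dict[str, dict[str, float]] = {}
    for limb in LIMBS:
        g_moment = _gain(gsd["moment"]) * bias[limb]
        gains[limb] = {
            "knee_ext_moment": g_moment,
            "knee_flex_moment": g_moment * _gain(gsd["flexor"]),
            "grf": _gain(gsd["grf"]),
            "act_ham": _gain(gsd["activation"]) * ham_bias,
            "act_quad": _gain(gsd["activation"]),
        }
    for sig in SIGNALS:
        for limb in LIMBS:
            strides = record.waveforms[sig][limb]
            gain = gains[limb][sig]
            peak = max((float(np.max(np.abs(s))) for s in strides), default=0.0)
            for i, arr in enumerate(strides):
                noisy = arr * gain
                if add_sd > 0 and peak > 0:
                    noisy = noisy + rng.normal(0.0, add_sd * peak, size=arr.shape)
                if sig == "grf":
                    noisy = np.clip(noisy, 0.0, None)
                elif sig.startswith("act"):
                    noisy = np.clip(noisy, 0.0, 1.2)
                strides[i] = noisy
    return record
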