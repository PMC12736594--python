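"""Signal processing and biomechanical feature extraction.

Pipeline per trial: zero-phase low-pass filtering (4th-order Butterworth,
6 Hz cutoff by default), stance segmentation from the vertical GRF, then the
observed feature set: dynamic H:Q ratio, limb-symmetry indices (knee moment,
GRF, stance time), early-stance co-contraction, time-to-peak knee flexion
moment, and stride-to-stride variability.  Extraction is deterministic.

Conventions (documented design choices): LSIs use the symmetric form
``100*(L-R)/mean(L,R)`` on peak-based per-limb summaries; the CCI is the
Falconer-Winter overlap over the first 30% of stance; integration is
trapezoidal; stance windows are half-open ``[onset, offset)`` with 0-based
indices; ties in time-to-peak resolve to the first maximum.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .config import RuleThresholds, SimulationConfig
from .waveforms import LIMBS, TrialRecord


class SignalError(ValueError):
    """Raised for signals that cannot be filtered or segmented."""


class FeatureError(ValueError):
    """Raised when a feature is undefined for the given inputs."""


@lru_cache(maxsize=32)
def _butter_coeffs(order: int, cutoff: float, fs: float):
    return sps.butter(order, cutoff, btype="low", fs=fs)


def zero_phase_lowpass(x: np.ndarray, fs: float, cutoff: float = 6.0,
                       order: int = 4) -> np.ndarray:
    """Forward-backward (zero phase lag) low-pass Butterworth filter.

    Accepts a 1-D signal or a 2-D array of signals (filtered along the last
    axis).  Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2.0 * cutoff:
        raise SignalError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    if x.shape[-1] <= 3 * (order + 1):
        raise SignalError(
            f"signal length {x.shape[-1]} too short for order-{order} filtfilt")
    b, a = _butter_coeffs(order, cutoff, fs)
    return sps.filtfilt(b, a, x, axis=-1)


def segment_stance(grf: np.ndarray, fs: float | None = None,
                   threshold_bw: float = 0.05) -> tuple[int, int]:
    """Half-open stance window ``[onset, offset)`` from a vertical GRF.

    Onset is the first sample strictly above ``threshold_bw`` (body weights),
    offset one past the last such sample.
    """
    grf = np.asarray(grf, dtype=float)
    above = np.flatnonzero(grf > threshold_bw)
    if above.size == 0:
        raise SignalError("no GRF sample exceeds the stance threshold")
    return int(above[0]), int(above[-1]) + 1


def compute_hq_dyn(flexor: np.ndarray, extensor: np.ndarray,
                   window: tuple[int, int], fs: float) -> float:
    """Stance integral ratio of |flexor| to |extensor| knee moment."""
    on, off = window
    dt = 1.0 / fs
    denom = np.trapezoid(np.abs(extensor[on:off]), dx=dt)
    if denom <= 0:
        raise FeatureError("zero extensor-moment stance integral")
    return float(np.trapezoid(np.abs(flexor[on:off]), dx=dt) / denom)


def compute_lsi(left: float, right: float) -> float:
    """Signed limb symmetry index, percent: ``100*(L-R)/(0.5*(L+R))``."""
    denom = 0.5 * (left + right)
    if denom <= 0:
        raise FeatureError("non-positive LSI denominator")
    return float(100.0 * (left - right) / denom)


def compute_cci(act_h: np.ndarray, act_q: np.ndarray,
                window: tuple[int, int], early_fraction: float = 0.30,
                fs: float = 1.0) -> float:
    """Falconer-Winter co-contraction index over early stance.

    ``2 * integral(min(h, q)) / (integral(h) + integral(q))`` over the first
    ``early_fraction`` of the stance window; bounded in [0, 1] for
    non-negative activations.
    """
    if not 0.0 < early_fraction <= 1.0:
        raise FeatureError("early_fraction must lie in (0, 1]")
    on, off = window
    n_early = max(int(round(early_fraction * (off - on))), 2)
    sl = slice(on, on + n_early)
    dt = 1.0 / fs
    ih = np.trapezoid(act_h[sl], dx=dt)
    iq = np.trapezoid(act_q[sl], dx=dt)
    if ih + iq <= 0:
        raise FeatureError("both activation integrals are zero")
    return float(2.0 * np.trapezoid(np.minimum(act_h[sl], act_q[sl]), dx=dt)
                 / (ih + iq))


def compute_ttp_kfm(flexor: np.ndarray, window: tuple[int, int],
                    fs: float | None = None) -> float:
    """Time of the (first) flexor-moment peak, percent of stance."""
    on, off = window
    if off - on < 2:
        raise FeatureError("stance window shorter than 2 samples")
    idx = int(np.argmax(flexor[on:off]))
    return float(100.0 * idx / (off - on - 1))


def compute_stride_cv(values) -> float:
    """Coefficient of variation (percent, SD with ddof=1) across strides."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise FeatureError("stride CV requires at least 2 strides")
    mean = values.mean()
    if mean <= 0:
        raise FeatureError("non-positive stride-summary mean")
    return float(100.0 * values.std(ddof=1) / mean)


def extract_waveform_features(trial: TrialRecord,
                              config: SimulationConfig) -> dict[str, float]:
    """The seven biomechanical features of one trial (no labels attached).

    Per limb and stride, all five signals are filtered together, stance is
    segmented on the filtered GRF, and stride-level quantities are computed;
    stride averages per limb feed the LSIs, and H:Qdyn / CCI / TTP are
    averaged over strides then limbs.
    """
    fs = config.fs
    per_limb: dict[str, dict[str, float]] = {}
    hq_limbs, cci_limbs, ttp_limbs, cv_limbs = [], [], [], []
    for limb in LIMBS:
        n_strides = len(trial.waveforms["grf"][limb])
        hq_s, cci_s, ttp_s = [], [], []
        peak_ext, peak_grf, stance_t = [], [], []
        for s in range(n_strides):
            stack = np.vstack([trial.waveforms[sig][limb][s]
                               for sig in ("knee_ext_moment", "knee_flex_moment",
                                           "grf", "act_ham", "act_quad")])
            filt = zero_phase_lowpass(stack, fs, config.filter_cutoff_hz,
                                      config.filter_order)
            ext, flex, grf, act_h, act_q = filt
            try:
                win = segment_stance(grf, fs)
            except SignalError as err:
                raise SignalError(f"{trial.trial_id}/{limb}/stride{s}: {err}")
            hq_s.append(compute_hq_dyn(flex, ext, win, fs))
            cci_s.append(compute_cci(act_h, act_q, win, fs=fs))
            ttp_s.append(compute_ttp_kfm(flex, win))
            on, off = win
            peak_ext.append(float(ext[on:off].max()))
            peak_grf.append(float(grf[on:off].max()))
            stance_t.append((off - on) / fs)
        hq_limbs.append(np.mean(hq_s))
        cci_limbs.append(np.mean(cci_s))
        ttp_limbs.append(np.mean(ttp_s))
        cv_limbs.append(compute_stride_cv(peak_ext))
        per_limb[limb] = {"peak_ext": float(np.mean(peak_ext)),
                          "peak_grf": float(np.mean(peak_grf)),
                          "stance_time": float(np.mean(stance_t))}
    return {
        "hq_dyn": float(np.mean(hq_limbs)),
        "lsi_knee_moment": compute_lsi(per_limb["left"]["peak_ext"],
                                       per_limb["right"]["peak_ext"]),
        "cci_early_stance": float(np.mean(cci_limbs)),
        "lsi_grf": compute_lsi(per_limb["left"]["peak_grf"],
                               per_limb["right"]["peak_grf"]),
        "lsi_stance_time": compute_lsi(per_limb["left"]["stance_time"],
                                       per_limb["right"]["stance_time"]),
        "ttp_kfm": float(np.mean(ttp_limbs)),
        "stride_cv": float(np.mean(cv_limbs)),
    }


def extract_feature_row(trial: TrialRecord, config: SimulationConfig,
                        thresholds: RuleThresholds | None = None) -> dict:
    """One observed-feature row for a trial: features, speed, and labels.

    Labels are recomputed here from the trial's stored latent features so
    that a row is self-contained; the stochastic flip (if any) is applied by
    the labeling stage on the assembled table.
    """
    from .labeling import apply_composite_rule  # local import, no cycle at module load

    thresholds = thresholds or RuleThresholds()
    try:
        feats = extract_waveform_features(trial, config)
    except (SignalError, FeatureError) as err:
        raise FeatureError(f"trial {trial.trial_id}: {err}") from err
    lat = trial.latent_features
    row = {"trial_id": trial.trial_id, "subject_id": trial.subject_id,
           "speed_band": trial.speed_band, "speed": trial.speed}
    row.update(feats)
    row.update({f"latent_{k}": v for k, v in lat.items()})
    row["label_latent"] = int(apply_composite_rule(
        lat["hq_dyn"], lat["lsi_knee_moment"], lat["cci_early_stance"],
        thresholds))
    return row
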