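"""Plain-text I/O for trial waveform bundles.

One CSV per trial, long format: ``stride`` and ``sample`` index columns
followed by one column per limb/signal (units in the header).  Stride
lengths may differ between strides and limbs; absent samples are left
empty.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .waveforms import LIMBS, SIGNALS, TrialRecord

_UNITS = {"knee_ext_moment": "N.m/kg", "knee_flex_moment": "N.m/kg",
          "grf": "BW", "act_ham": "norm", "act_quad": "norm"}


def _col(limb: str, sig: str) -> str:
    return f"{limb}_{sig}[{_UNITS[sig]}]"


def write_waveform_bundle(trial: TrialRecord, path: str | Path) -> Path:
    """Write one trial's waveforms (plus a duration column) to CSV."""
    path = Path(path)
    frames = []
    n_strides = trial.n_strides
    for s in range(n_strides):
        lengths = [len(trial.waveforms["grf"][limb][s]) for limb in LIMBS]
        n = max(lengths)
        block = {"stride": np.full(n, s, dtype=int), "sample": np.arange(n)}
        for limb in LIMBS:
            for sig in SIGNALS:
                arr = trial.waveforms[sig][limb][s]
                col = np.full(n, np.nan)
                col[:len(arr)] = arr
                block[_col(limb, sig)] = col
        frames.append(pd.DataFrame(block))
    df = pd.concat(frames, ignore_index=True)
    for limb in LIMBS:
        df[f"{limb}_stance_duration[s]"] = np.nan
        for s in range(n_strides):
            df.loc[df["stride"] == s, f"{limb}_stance_duration[s]"] = (
                trial.stance_durations[limb][s])
    df.to_csv(path, index=False)
    return path


def read_waveform_bundle(path: str | Path, trial_id: str, subject_id: str,
                         speed_band: int, speed: float) -> TrialRecord:
    """Rebuild a :class:`TrialRecord` (without latent features) from CSV."""
    df = pd.read_csv(path)
    waveforms = {sig: {limb: [] for limb in LIMBS} for sig in SIGNALS}
    durations = {limb: [] for limb in LIMBS}
    for s, block in df.groupby("stride"):
        for limb in LIMBS:
            for sig in SIGNALS:
                arr = block[_col(limb, sig)].to_numpy(dtype=float)
                waveforms[sig][limb].append(arr[~np.isnan(arr)])
            durations[limb].append(
                float(block[f"{limb}_stance_duration[s]"].iloc[0]))
    return TrialRecord(trial_id=trial_id, subject_id=subject_id,
                       speed_band=speed_band, speed=speed,
                       waveforms=waveforms,
                       stance_durations={limb: np.asarray(d)
                                         for limb, d in durations.items()})
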