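"""Thin adapters for on-disk formats.

Raw continuous EEG comes in as BioSemi BDF or EDF+ (delegated to MNE);
epoched tensors travel in the HDF5 container defined in ``containers``;
trial metadata is CSV with columns subject, group, condition, trial, rt_ms,
accuracy; electrode positions are plain text (label x y z per line, see
``montage``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EpochSet, load_epochs_h5, save_epochs_h5  # noqa: F401
from .montage import read_montage, write_montage  # noqa: F401

TRIAL_COLUMNS = ["subject", "group", "condition", "trial", "rt_ms", "accuracy"]


def read_raw(path):
    """Read a continuous BioSemi BDF or EDF+ recording (returns an MNE Raw)."""
    import mne

    path = str(path)
    if path.lower().endswith(".bdf"):
        return mne.io.read_raw_bdf(path, preload=True, verbose="error")
    return mne.io.read_raw_edf(path, preload=True, verbose="error")


def epochs_from_raw(
    raw,
    onsets_s: np.ndarray,
    pre_lock_tf: int,
    n_times: int,
    **meta,
) -> EpochSet:
    """Cut fixed-length epochs around event onsets from a continuous Raw."""
    fs = raw.info["sfreq"]
    data = raw.get_data() * 1e6  # volts -> microvolts
    starts = (np.asarray(onsets_s) * fs).round().astype(int) - pre_lock_tf
    trials = np.stack([data[:, s : s + n_times] for s in starts])
    return EpochSet(
        subject=meta.pop("subject", ""),
        group=meta.pop("group", ""),
        condition=meta.pop("condition", ""),
        lock=meta.pop("lock", "stimulus"),
        data=trials,
        sampling_rate=fs,
        pre_lock_tf=pre_lock_tf,
        trial_meta=meta.pop("trial_meta", None),
    )


def read_trial_metadata(path) -> pd.DataFrame:
    """Read the per-trial behaviour CSV and validate its columns."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial metadata is missing columns {missing}")
    df["accuracy"] = df["accuracy"].astype(bool)
    return df


def write_trial_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in TRIAL_COLUMNS if c in df])
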