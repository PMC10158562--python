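"""In-memory containers for epoched and averaged EEG.

``EpochSet`` holds a single subject's trials x electrodes x time-frames
tensor together with its lock convention (stimulus- or response-locked) and
per-trial behaviour (reaction time, accuracy). ``Erp`` is the trial average
(an evoked response). ``CombinedErp`` is the stimulus/response concatenation
produced by overlap removal. HDF5 round-trip I/O lives here too so that the
tensors travel with their metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochSet", "Erp", "CombinedErp", "save_epochs_h5", "load_epochs_h5"]

TRIAL_META_COLUMNS = ("trial", "rt_ms", "accuracy")


@dataclass
class EpochSet:
    """Per-subject epoched EEG.

    ``data`` is trials x electrodes x TFs in microvolts. ``pre_lock_tf`` is
    the number of frames recorded before the lock event (picture onset for
    stimulus-locked epochs; for response-locked epochs the lock event, vocal
    onset, falls *after* the epoch end, so ``pre_lock_tf`` equals
    ``n_times + end_offset_tf``).
    """

    subject: str
    group: str
    condition: str
    lock: str  # "stimulus" | "response"
    data: np.ndarray
    sampling_rate: float
    pre_lock_tf: int
    trial_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x electrodes x TFs")
        if self.lock not in ("stimulus", "response"):
            raise ValueError(f"unknown lock type {self.lock!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite values")
        if self.trial_meta is None:
            self.trial_meta = pd.DataFrame(
                {"trial": np.arange(self.n_trials), "rt_ms": np.nan, "accuracy": True}
            )
        if len(self.trial_meta) != self.n_trials:
            raise ValueError("trial_meta rows must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to the lock event."""
        step = 1000.0 / self.sampling_rate
        if self.lock == "stimulus":
            start = -self.pre_lock_tf
        else:
            # epoch ends pre_lock_tf - n_times frames before the lock event
            start = -self.pre_lock_tf
        return (np.arange(self.n_times) + start) * step

    def with_data(self, data: np.ndarray, trial_mask: np.ndarray | None = None) -> "EpochSet":
        meta = self.trial_meta
        if trial_mask is not None:
            meta = meta.loc[np.asarray(trial_mask)].reset_index(drop=True)
        return replace(self, data=np.asarray(data, dtype=float), trial_meta=meta)


@dataclass
class Erp:
    """Averaged evoked response: electrodes x TFs in microvolts."""

    data: np.ndarray
    sampling_rate: float
    pre_lock_tf: int
    lock: str = "stimulus"
    n_trials_averaged: int = 0
    subject: str = ""
    group: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Erp data must be electrodes x TFs")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        return (np.arange(self.n_times) - self.pre_lock_tf) * step

    def time_to_tf(self, t_ms: float) -> int:
        """Nearest frame index for a latency in ms relative to the lock."""
        idx = int(np.argmin(np.abs(self.times_ms - t_ms)))
        return idx


@dataclass
class CombinedErp:
    """Stimulus- and response-locked ERP concatenated after overlap removal.

    Covers picture onset up to ``end_offset_tf`` frames before vocal onset.
    ``boundary_tf`` is the frame at which the response-locked portion begins.
    """

    data: np.ndarray
    sampling_rate: float
    boundary_tf: int
    source_rt_ms: float
    subject: str = ""
    group: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("CombinedErp data must be electrodes x TFs")
        if not 0 <= self.boundary_tf <= self.data.shape[1]:
            raise ValueError("boundary_tf outside data")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def as_erp(self) -> Erp:
        """View as an Erp time-locked to picture onset (no pre-lock frames)."""
        return Erp(
            self.data,
            self.sampling_rate,
            pre_lock_tf=0,
            lock="stimulus",
            subject=self.subject,
            group=self.group,
            condition=self.condition,
        )


def save_epochs_h5(path, epoch_sets: list[EpochSet]) -> None:
    """Write a list of EpochSets to one HDF5 container with metadata."""
    with h5py.File(path, "w") as fh:
        for i, ep in enumerate(epoch_sets):
            grp = fh.create_group(f"epochs/{i:04d}")
            grp.create_dataset("data", data=ep.data, compression="gzip")
            grp.attrs.update(
                subject=ep.subject,
                group=ep.group,
                condition=ep.condition,
                lock=ep.lock,
                sampling_rate=ep.sampling_rate,
                pre_lock_tf=ep.pre_lock_tf,
            )
            grp.create_dataset("rt_ms", data=ep.trial_meta["rt_ms"].to_numpy(float))
            grp.create_dataset(
                "accuracy", data=ep.trial_meta["accuracy"].to_numpy(bool)
            )
            grp.create_dataset("trial", data=ep.trial_meta["trial"].to_numpy(int))


def load_epochs_h5(path) -> list[EpochSet]:
    out = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh["epochs"]):
            grp = fh[f"epochs/{key}"]
            meta = pd.DataFrame(
                {
                    "trial": grp["trial"][()],
                    "rt_ms": grp["rt_ms"][()],
                    "accuracy": grp["accuracy"][()].astype(bool),
                }
            )
            out.append(
                EpochSet(
                    subject=str(grp.attrs["subject"]),
                    group=str(grp.attrs["group"]),
                    condition=str(grp.attrs["condition"]),
                    lock=str(grp.attrs["lock"]),
                    data=grp["data"][()],
                    sampling_rate=float(grp.attrs["sampling_rate"]),
                    pre_lock_tf=int(grp.attrs["pre_lock_tf"]),
                    trial_meta=meta,
                )
            )
    return out
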