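"""Reaction-time filtering, response-locked epoching and overlap removal.

The analysis needs one ERP per subject covering picture onset up to shortly
before articulation. Stimulus-locked and response-locked averages overlap in
the middle of the trial; the overlap is removed by keeping the
stimulus-locked ERP up to ``round(RT * fs / 1000) - 300`` frames after
onset and appending the full 250-frame response-locked ERP, so the
concatenation covers exactly picture onset to 50 frames (about 100 ms)
before vocal onset. Group grand averages use the group mean RT; individual
ERPs use the subject's own mean RT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CombinedErp, EpochSet, Erp

__all__ = [
    "rt_filter",
    "RtExclusionReport",
    "epoch_response_locked",
    "remove_overlap_concatenate",
    "ms_to_tf",
]


def ms_to_tf(ms: float, fs: float) -> int:
    """ms -> frames, round-half-away-from-zero, applied once per quantity."""
    x = ms * fs / 1000.0
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class RtExclusionReport:
    n_total: int
    n_too_fast: int
    n_too_slow: int
    n_error: int
    n_kept: int


def rt_filter(
    trials: pd.DataFrame, lo: float = 500.0, hi: float = 2000.0
) -> tuple[pd.DataFrame, RtExclusionReport]:
    """Remove RT outliers and response errors from a trial table.

    Keeps correct trials with ``lo <= RT <= hi`` (defaults 500 and 2000 ms).
    ``trials`` needs columns ``rt_ms`` and ``accuracy``.
    """
    rt = trials["rt_ms"].to_numpy(float)
    acc = trials["accuracy"].to_numpy(bool)
    too_fast = rt < lo
    too_slow = rt > hi
    error = ~acc & ~too_fast & ~too_slow
    keep = acc & ~too_fast & ~too_slow
    report = RtExclusionReport(
        n_total=len(trials),
        n_too_fast=int(too_fast.sum()),
        n_too_slow=int(too_slow.sum()),
        n_error=int(error.sum()),
        n_kept=int(keep.sum()),
    )
    return trials.loc[keep].reset_index(drop=True), report


def epoch_response_locked(
    trial_signals: np.ndarray,
    rts_ms: np.ndarray,
    sampling_rate: float,
    onset_tf: int,
    length_tf: int = 250,
    end_offset_tf: int = 50,
    trial_meta: pd.DataFrame | None = None,
    **epoch_kwargs,
) -> tuple[EpochSet, int]:
    """Cut response-locked epochs from continuous per-trial signals.

    Parameters
    ----------
    trial_signals : ndarray (trials x electrodes x frames)
        Continuous segments; ``onset_tf`` is the frame index of picture onset.
    rts_ms : per-trial vocal onset latency relative to picture onset.

    Each epoch ends ``end_offset_tf`` frames before vocal onset (to exclude
    pre-articulatory motor artifacts) and spans ``length_tf`` frames. Trials
    whose window would precede picture onset are dropped; the drop count is
    returned.
    """
    x = np.asarray(trial_signals, float)
    rts_ms = np.asarray(rts_ms, float)
    rt_tf = np.array([ms_to_tf(rt, sampling_rate) for rt in rts_ms])
    start = rt_tf - end_offset_tf - length_tf  # relative to picture onset
    keep = (start >= 0) & (onset_tf + rt_tf - end_offset_tf <= x.shape[2])
    n_dropped = int((~keep).sum())
    cut = (
        np.stack(
            [
                x[t, :, onset_tf + s0 : onset_tf + s0 + length_tf]
                for t, s0 in zip(np.where(keep)[0], start[keep])
            ]
        )
        if keep.any()
        else np.empty((0, x.shape[1], length_tf))
    )
    meta = None
    if trial_meta is not None:
        meta = trial_meta.loc[keep].reset_index(drop=True)
    epochs = EpochSet(
        subject=epoch_kwargs.pop("subject", ""),
        group=epoch_kwargs.pop("group", ""),
        condition=epoch_kwargs.pop("condition", ""),
        lock="response",
        data=cut,
        sampling_rate=sampling_rate,
        pre_lock_tf=length_tf + end_offset_tf,
        trial_meta=meta,
    )
    return epochs, n_dropped


def remove_overlap_concatenate(
    stim: Erp,
    resp: Erp,
    mean_rt_ms: float,
    end_offset_tf: int = 50,
) -> CombinedErp:
    """Concatenate stimulus- and response-locked ERPs without their overlap.

    Keeps post-onset stimulus-locked frames ``[0, round(RT*fs/1000) - 300)``
    and appends all response-locked frames, yielding exactly
    ``round(RT*fs/1000) - end_offset_tf`` frames from picture onset to
    ``end_offset_tf`` frames before articulation. The cut RT is the group
    mean for grand averages and the subject's own mean for individual ERPs.
    """
    if stim.lock != "stimulus" or resp.lock != "response":
        raise ValueError("arguments must be a stimulus- and a response-locked Erp")
    if abs(stim.sampling_rate - resp.sampling_rate) > 1e-9:
        raise ValueError("sampling rates differ")
    fs = stim.sampling_rate
    resp_len = resp.n_times
    rt_tf = ms_to_tf(mean_rt_ms, fs)
    n_stim = rt_tf - resp_len - end_offset_tf
    min_rt_ms = (resp_len + end_offset_tf) * 1000.0 / fs
    if n_stim < 0:
        raise ValueError(
            f"mean RT {mean_rt_ms:.0f} ms is too short for overlap removal; "
            f"minimum supportable RT is {min_rt_ms:.1f} ms"
        )
    stim_post = stim.data[:, stim.pre_lock_tf :]
    if n_stim > stim_post.shape[1]:
        raise ValueError(
            "stimulus-locked ERP too short to reach the overlap cut "
            f"(need {n_stim} post-onset frames, have {stim_post.shape[1]})"
        )
    data = np.concatenate([stim_post[:, :n_stim], resp.data], axis=1)
    return CombinedErp(
        data=data,
        sampling_rate=fs,
        boundary_tf=n_stim,
        source_rt_ms=float(mean_rt_ms),
        subject=stim.subject,
        group=stim.group,
        condition=stim.condition,
    )
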