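"""Single-subject preprocessing: filter, re-reference, reject, interpolate, average.

The canonical order is band-pass filter -> average reference -> artifact /
error-trial rejection -> bad-electrode interpolation -> trial averaging.
Filtering is a second-order zero-phase (forward-backward) Butterworth
band-pass, i.e. acausal with -12 dB/octave roll-off per pass. Artifact
rejection uses a deterministic absolute-amplitude criterion (default
+/-100 microvolts) standing in for visual inspection; it also removes
error-response trials so only correct productions are averaged. Bad channels
are rebuilt by spherical-spline interpolation on the montage sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import EpochSet, Erp
from .montage import Montage

__all__ = [
    "bandpass_filter",
    "rereference_average",
    "baseline_correct",
    "reject_artifacts",
    "RejectionReport",
    "interpolate_bad_electrodes",
    "average_erp",
    "TooFewTrialsError",
    "preprocess_epochs",
]

MAX_BAD_FRACTION = 0.20  # contaminated-electrode ceiling (20% of channels)


class TooFewTrialsError(RuntimeError):
    """Raised when a subject retains fewer trials than the averaging minimum."""


def bandpass_filter(epochs: EpochSet, hp: float = 0.2, lp: float = 30.0) -> EpochSet:
    """Zero-phase second-order Butterworth band-pass, per trial and electrode.

    Forward-backward application (``sosfiltfilt``) makes the filter acausal
    with zero phase distortion; edges are padded by reflection.
    """
    nyq = epochs.sampling_rate / 2.0
    if not (0 <= hp < lp < nyq):
        raise ValueError(
            f"corner frequencies must satisfy 0 <= hp < lp < {nyq} Hz "
            f"(got hp={hp}, lp={lp})"
        )
    if hp == 0:
        sos = butter(2, lp / nyq, btype="low", output="sos")
    else:
        sos = butter(2, [hp / nyq, lp / nyq], btype="band", output="sos")
    out = sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.with_data(out)


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the common average: subtract the electrode mean per frame."""
    if epochs.n_electrodes < 2:
        raise ValueError("average reference needs at least 2 electrodes")
    out = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.with_data(out)


def baseline_correct(epochs: EpochSet, window_tf: tuple[int, int] | None = None) -> EpochSet:
    """Subtract the per-trial, per-electrode mean over a baseline window.

    Defaults to the full pre-lock interval of stimulus-locked epochs.
    Response-locked epochs are conventionally left uncorrected (there is no
    consensus baseline before articulation); passing one here still works if
    a window is given explicitly.
    """
    if window_tf is None:
        if epochs.lock != "stimulus":
            raise ValueError(
                "no default baseline for response-locked epochs; pass window_tf"
            )
        window_tf = (0, epochs.pre_lock_tf)
    lo, hi = window_tf
    if not (0 <= lo < hi <= epochs.n_times):
        raise ValueError(f"baseline window {window_tf} outside epoch")
    base = epochs.data[:, :, lo:hi].mean(axis=2, keepdims=True)
    return epochs.with_data(epochs.data - base)


@dataclass
class RejectionReport:
    subject: str
    n_total: int
    n_artifact: int
    n_error: int
    n_kept: int
    kept_mask: np.ndarray


def reject_artifacts(
    epochs: EpochSet, abs_threshold: float = 100.0, drop_errors: bool = True
) -> tuple[EpochSet, RejectionReport]:
    """Drop trials exceeding an absolute amplitude and error-response trials.

    A trial is an artifact if any sample exceeds ``abs_threshold`` in
    magnitude (eyeblinks and motor artifacts are large-amplitude events).
    Error productions are dropped from ``trial_meta['accuracy']`` so that
    only correct trials reach the average.
    """
    if abs_threshold <= 0:
        raise ValueError("abs_threshold must be positive")
    artifact = np.abs(epochs.data).max(axis=(1, 2)) > abs_threshold
    if drop_errors and "accuracy" in epochs.trial_meta:
        error = ~epochs.trial_meta["accuracy"].to_numpy(bool)
    else:
        error = np.zeros(epochs.n_trials, dtype=bool)
    keep = ~(artifact | error)
    report = RejectionReport(
        subject=epochs.subject,
        n_total=epochs.n_trials,
        n_artifact=int(artifact.sum()),
        n_error=int((error & ~artifact).sum()),
        n_kept=int(keep.sum()),
        kept_mask=keep,
    )
    return epochs.with_data(epochs.data[keep], trial_mask=keep), report


def _spline_interpolation_matrix(
    montage: Montage, bad_idx: np.ndarray, order: int = 4, reg: float = 1e-5
):
    """Spherical-spline mapping from good channels to bad channel positions."""
    from mne.channels.interpolation import _make_interpolation_matrix

    good = np.setdiff1d(np.arange(montage.n_electrodes), bad_idx)
    return good, _make_interpolation_matrix(
        montage.positions[good], montage.positions[bad_idx], alpha=reg
    )


def interpolate_bad_electrodes(
    epochs: EpochSet, montage: Montage, bad: list[str]
) -> EpochSet:
    """Rebuild contaminated channels by spherical-spline interpolation.

    At most 20% of channels may be interpolated; beyond that the spatial
    information cannot be considered recoverable and the subject should be
    excluded instead.
    """
    if not bad:
        return epochs
    bad_idx = np.array(sorted(montage.index(b) for b in bad))
    frac = len(bad_idx) / montage.n_electrodes
    if frac > MAX_BAD_FRACTION:
        raise ValueError(
            f"{len(bad_idx)} of {montage.n_electrodes} electrodes are bad "
            f"({frac:.0%}); the interpolation limit is "
            f"{MAX_BAD_FRACTION:.0%} of channels"
        )
    good, interp = _spline_interpolation_matrix(montage, bad_idx)
    out = epochs.data.copy()
    # interp is (n_bad, n_good); apply per trial across all frames at once
    out[:, bad_idx, :] = np.einsum("bg,tgf->tbf", interp, epochs.data[:, good, :])
    return epochs.with_data(out)


def average_erp(epochs: EpochSet, min_trials: int = 55) -> Erp:
    """Average surviving trials into an evoked response.

    Raises
    ------
    TooFewTrialsError
        If fewer than ``min_trials`` trials survive; the subject is excluded
        from group statistics rather than averaged on thin data.
    """
    if epochs.n_trials < min_trials:
        raise TooFewTrialsError(
            f"subject {epochs.subject!r} ({epochs.condition}): "
            f"{epochs.n_trials} trials < minimum {min_trials}"
        )
    return Erp(
        data=epochs.data.mean(axis=0),
        sampling_rate=epochs.sampling_rate,
        pre_lock_tf=epochs.pre_lock_tf,
        lock=epochs.lock,
        n_trials_averaged=epochs.n_trials,
        subject=epochs.subject,
        group=epochs.group,
        condition=epochs.condition,
    )


def preprocess_epochs(
    epochs: EpochSet,
    montage: Montage | None = None,
    hp: float = 0.2,
    lp: float = 30.0,
    abs_threshold: float = 100.0,
    bad: list[str] | None = None,
    baseline: bool = True,
    min_trials: int = 55,
) -> tuple[Erp, RejectionReport]:
    """Run the full single-subject chain in canonical order and average.

    Order: filter -> average reference -> baseline (stimulus-locked only)
    -> artifact/error rejection -> bad-channel interpolation -> average.
    """
    ep = bandpass_filter(epochs, hp, lp)
    ep = rereference_average(ep)
    if baseline and ep.lock == "stimulus":
        ep = baseline_correct(ep)
    ep, report = reject_artifacts(ep, abs_threshold)
    if bad:
        if montage is None:
            raise ValueError("montage required to interpolate bad electrodes")
        ep = interpolate_bad_electrodes(ep, montage, bad)
        ep = rereference_average(ep)  # restore exact average reference
    return average_erp(ep, min_trials=min_trials), report
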