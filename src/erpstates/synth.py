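"""Synthetic multi-group picture-naming EEG with planted microstate structure.

Each trial is simulated as one continuous segment running from 50 frames
before picture onset to beyond the slowest allowed vocal onset, so that
stimulus-locked and response-locked epochs cut from it are mutually
consistent. The scalp signal is a sum of planted template-map states —
stimulus-anchored early components and response-anchored pre-articulatory
states — with raised-cosine amplitude envelopes, plus spatially smooth
Gaussian noise re-centred to the average reference. Group structure enters
as a latency shift and an amplitude scale (younger groups: delayed, larger
components, slower responses); the within-subject condition factor (an
age-of-acquisition-like manipulation) enters as an amplitude change in a
late window. Reaction times follow a truncated normal per group; accuracy a
logistic model with group and condition offsets.

Everything is a pure function of the design's seed, per subject and
condition, so response-locked epochs can be re-cut from bit-identical
continuous trials without storing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .containers import EpochSet
from .montage import Montage
from .topo import GFP_EPS, normalize_map, spatial_correlation

__all__ = [
    "StateSpec",
    "SyntheticDesign",
    "default_design",
    "demo_design",
    "make_template_maps",
    "simulate_epochs",
    "simulate_response_locked",
    "rt_moments",
    "state_windows",
]


@dataclass(frozen=True)
class StateSpec:
    """One planted microstate: which template, when, and how strongly.

    ``anchor`` decides the time origin: ``"stimulus"`` states are defined
    relative to picture onset (and take the group latency shift);
    ``"response"`` states are defined relative to each trial's vocal onset.
    """

    label: str
    onset_ms: float
    offset_ms: float
    amplitude_uv: float
    anchor: str = "stimulus"
    envelope: str = "plateau"  # or "hann": peaked, for latency-defined components


@dataclass(frozen=True)
class SyntheticDesign:
    """Full specification of a simulated multi-group naming experiment."""

    n_groups: int = 4
    n_subjects_per_group: int = 20
    n_trials: int = 60  # per condition
    n_electrodes: int = 128
    sampling_rate: float = 512.0
    group_names: tuple[str, ...] = (
        "children",
        "young_adolescents",
        "older_adolescents",
        "adults",
    )
    condition_names: tuple[str, ...] = ("early_acquired", "late_acquired")
    state_sequence: tuple[StateSpec, ...] = (
        # the P1-like state is peaked (hann) so its GFP maximum has a
        # well-defined latency; later states are sustained plateaus
        StateSpec("A", 60.0, 130.0, 3.0, envelope="hann"),
        StateSpec("B", 130.0, 200.0, 2.5),
        StateSpec("C", 200.0, 290.0, 2.5),
        StateSpec("D", 290.0, 400.0, 2.0),
        StateSpec("E", 400.0, 480.0, 1.8),
        StateSpec("F", -350.0, -220.0, 2.0, anchor="response"),
        StateSpec("G", -220.0, -120.0, 2.2, anchor="response"),
    )
    # youngest -> oldest: delayed latencies, larger amplitudes, slower RTs
    group_latency_shift_ms: tuple[float, ...] = (60.0, 30.0, 10.0, 0.0)
    group_amplitude_scale: tuple[float, ...] = (1.4, 1.2, 1.1, 1.0)
    condition_effect_window_ms: tuple[float, float] = (300.0, 450.0)
    condition_effect_delta_uv: float = 0.6  # added to late-acquired states in window
    noise_sd_uv: float = 1.0
    spatial_noise_smoothness: float = 0.5  # kernel length on unit-sphere chords
    ramp_ms: float = 10.0
    # group means stay inside the overlap-removal coverage limit: with 300
    # stimulus-locked frames (50 pre-onset) and a 250-frame response-locked
    # epoch, exact onset-to-(RT-50TF) coverage needs mean RT <= ~1074 ms
    rt_mean_ms: tuple[float, ...] = (980.0, 920.0, 870.0, 820.0)
    rt_sd_ms: float = 150.0
    rt_min_ms: float = 500.0
    rt_max_ms: float = 2000.0
    accuracy_logit_intercept: float = 3.2
    accuracy_logit_group: tuple[float, ...] = (-0.9, -0.4, -0.3, 0.0)
    accuracy_logit_condition: tuple[float, ...] = (0.0, -0.5)
    pre_lock_tf: int = 50
    stim_epoch_tf: int = 300
    resp_epoch_tf: int = 250
    resp_end_offset_tf: int = 50
    min_separation: float = 0.5
    seed: int = 0
    template_maps: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_groups != len(self.group_names):
            raise ValueError("group_names must match n_groups")
        for tup in (
            self.group_latency_shift_ms,
            self.group_amplitude_scale,
            self.rt_mean_ms,
            self.accuracy_logit_group,
        ):
            if len(tup) != self.n_groups:
                raise ValueError("per-group parameter tuples must match n_groups")
        if not (0 <= self.rt_min_ms < self.rt_max_ms):
            raise ValueError("need 0 <= rt_min < rt_max")
        for anchor in ("stimulus", "response"):
            seq = [s for s in self.state_sequence if s.anchor == anchor]
            for a, b in zip(seq, seq[1:]):
                if b.onset_ms < a.offset_ms:
                    raise ValueError(
                        f"{anchor}-anchored state windows must be ordered and "
                        f"non-overlapping ({a.label} vs {b.label})"
                    )
        if self.template_maps is not None:
            t = np.asarray(self.template_maps, float)
            if np.abs(t.mean(axis=1)).max() > 1e-10:
                raise ValueError("planted template maps must be average-referenced")
        # the shifted stimulus sequence must fit the simulated support
        max_shift = max(self.group_latency_shift_ms)
        last = max(
            (s.offset_ms for s in self.state_sequence if s.anchor == "stimulus"),
            default=0.0,
        )
        if last + max_shift > self._post_onset_tf() * 1000.0 / self.sampling_rate:
            raise ValueError(
                "shifted stimulus-anchored state sequence exceeds the simulated window"
            )

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(s.label for s in self.state_sequence))

    @property
    def n_maps(self) -> int:
        return len(self.state_labels)

    def _post_onset_tf(self) -> int:
        """Frames simulated after picture onset (covers the slowest response)."""
        rt_max_tf = _ms_to_tf(self.rt_max_ms, self.sampling_rate)
        return max(self.stim_epoch_tf - self.pre_lock_tf, rt_max_tf)

    def n_continuous_tf(self) -> int:
        return self.pre_lock_tf + self._post_onset_tf()


def _ms_to_tf(ms: float, fs: float) -> int:
    """Round-half-away-from-zero ms -> frame conversion (applied once per quantity)."""
    x = ms * fs / 1000.0
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def default_design(seed: int = 0, n_electrodes: int = 128) -> SyntheticDesign:
    """The emulated study: 4 groups x 2 conditions x 20 subjects, 512 Hz."""
    return SyntheticDesign(seed=seed, n_electrodes=n_electrodes)


def demo_design(seed: int = 0) -> SyntheticDesign:
    """Scaled-down profile for end-to-end runs: 5 subjects/group, 32 electrodes."""
    return SyntheticDesign(
        seed=seed, n_subjects_per_group=5, n_electrodes=32, n_trials=40
    )


# ---------------------------------------------------------------------------
# template maps


def make_template_maps(
    n_maps: int,
    montage: Montage,
    min_separation: float = 0.5,
    seed: int = 0,
    max_attempts_per_map: int = 500,
) -> np.ndarray:
    """Generate smooth, mutually distinct unit-GFP template maps.

    Each candidate is the scalp field of a randomly placed tangentially or
    radially oriented dipole in a homogeneous sphere, average-referenced and
    normalised to unit GFP. Rejection sampling keeps only candidates whose
    absolute spatial correlation with every accepted map is at most
    ``min_separation``.

    Returns
    -------
    ndarray, shape (n_maps, n_electrodes)
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    if not (0 <= min_separation < 1):
        raise ValueError("min_separation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    pos = montage.positions
    maps: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_map * n_maps
    while len(maps) < n_maps:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n_maps} maps with pairwise |r| <= "
                f"{min_separation} on this montage within {budget} attempts"
            )
        attempts += 1
        # dipole inside the head, away from the surface
        src = rng.normal(size=3)
        src = src / np.linalg.norm(src) * rng.uniform(0.2, 0.7)
        src[2] = abs(src[2]) * 0.8  # keep sources in the upper head
        moment = rng.normal(size=3)
        moment /= np.linalg.norm(moment)
        d = pos - src
        r3 = np.linalg.norm(d, axis=1) ** 3
        v = d @ moment / r3
        if np.sqrt(np.mean((v - v.mean()) ** 2)) <= GFP_EPS:
            continue
        v = normalize_map(v)
        if all(abs(spatial_correlation(v, m)) <= min_separation for m in maps):
            maps.append(v)
    return np.array(maps)


def _smoothing_matrix(montage: Montage, length: float) -> np.ndarray:
    """Row-normalised Gaussian kernel on chord distances (unit noise variance)."""
    d = np.linalg.norm(
        montage.positions[:, None, :] - montage.positions[None, :, :], axis=2
    )
    k = np.exp(-(d**2) / (2.0 * length**2))
    return k / np.linalg.norm(k, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# trial synthesis


def state_windows(
    design: SyntheticDesign, group_idx: int, condition_idx: int, rt_ms: float | None = None
) -> list[tuple[str, float, float, float]]:
    """Ground-truth (label, onset_ms, offset_ms, amplitude_uv) windows.

    Times are relative to picture onset with the group latency shift applied
    to stimulus-anchored states; response-anchored states need ``rt_ms``.
    The condition amplitude delta and group amplitude scale are folded into
    the returned amplitude.
    """
    shift = design.group_latency_shift_ms[group_idx]
    scale = design.group_amplitude_scale[group_idx]
    w_lo, w_hi = design.condition_effect_window_ms
    out = []
    for s in design.state_sequence:
        if s.anchor == "stimulus":
            on, off = s.onset_ms + shift, s.offset_ms + shift
        else:
            if rt_ms is None:
                continue
            on, off = s.onset_ms + rt_ms, s.offset_ms + rt_ms
        amp = s.amplitude_uv
        if condition_idx == 1 and s.anchor == "stimulus":
            # the planted condition effect hits states overlapping its window
            if min(off, w_hi + shift) > max(on, w_lo + shift):
                amp += design.condition_effect_delta_uv
        out.append((s.label, on, off, amp * scale))
    return out


def _envelope(
    times_ms: np.ndarray, on: float, off: float, ramp: float, shape: str = "plateau"
) -> np.ndarray:
    """Amplitude envelope between on and off.

    ``plateau``: raised-cosine ramps (inside the window) around a flat top;
    ``hann``: a single raised cosine peaking at the window centre.
    """
    env = np.zeros_like(times_ms)
    inside = (times_ms >= on) & (times_ms <= off)
    if shape == "hann":
        env[inside] = 0.5 * (1 - np.cos(2 * np.pi * (times_ms[inside] - on) / (off - on)))
        return env
    ramp = min(ramp, (off - on) / 2.0)
    env[inside] = 1.0
    if ramp > 0:
        up = inside & (times_ms < on + ramp)
        env[up] = 0.5 * (1 - np.cos(np.pi * (times_ms[up] - on) / ramp))
        dn = inside & (times_ms > off - ramp)
        env[dn] = 0.5 * (1 - np.cos(np.pi * (off - times_ms[dn]) / ramp))
    return env


def _templates(design: SyntheticDesign, montage: Montage) -> np.ndarray:
    if design.template_maps is not None:
        t = np.asarray(design.template_maps, float)
        if t.shape != (design.n_maps, montage.n_electrodes):
            raise ValueError("template_maps shape does not match design/montage")
        return t
    return make_template_maps(
        design.n_maps, montage, design.min_separation, seed=design.seed
    )


def _subject_rng(design: SyntheticDesign, g: int, s: int, c: int) -> np.random.Generator:
    return np.random.default_rng([design.seed, 1000 + g, 2000 + s, 3000 + c])


def _draw_behavior(
    design: SyntheticDesign, rng: np.random.Generator, g: int, c: int
) -> tuple[np.ndarray, np.ndarray]:
    loc, sd = design.rt_mean_ms[g], design.rt_sd_ms
    a = (design.rt_min_ms - loc) / sd
    b = (design.rt_max_ms - loc) / sd
    rts = truncnorm.rvs(a, b, loc=loc, scale=sd, size=design.n_trials, random_state=rng)
    logit = (
        design.accuracy_logit_intercept
        + design.accuracy_logit_group[g]
        + design.accuracy_logit_condition[c]
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    acc = rng.random(design.n_trials) < p
    return rts, acc


def _simulate_continuous(
    design: SyntheticDesign,
    templates: np.ndarray,
    smooth: np.ndarray,
    g: int,
    s: int,
    c: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All trials of one subject x condition as continuous segments.

    Returns (data: trials x electrodes x frames, rt_ms, accuracy); frame 0 is
    ``pre_lock_tf`` frames before picture onset. Deterministic in the design
    seed and the (group, subject, condition) indices.
    """
    rng = _subject_rng(design, g, s, c)
    rts, acc = _draw_behavior(design, rng, g, c)
    n_tf = design.n_continuous_tf()
    n_el = templates.shape[1]
    times = (np.arange(n_tf) - design.pre_lock_tf) * 1000.0 / design.sampling_rate
    label_index = {lab: i for i, lab in enumerate(design.state_labels)}

    data = np.empty((design.n_trials, n_el, n_tf))
    for t in range(design.n_trials):
        sig = np.zeros((n_el, n_tf))
        shapes = {s.label: s.envelope for s in design.state_sequence}
        for lab, on, off, amp in state_windows(design, g, c, rt_ms=rts[t]):
            env = _envelope(times, on, off, design.ramp_ms, shapes[lab])
            sig += amp * np.outer(templates[label_index[lab]], env)
        if design.noise_sd_uv > 0:
            noise = smooth @ rng.standard_normal((n_el, n_tf))
            noise -= noise.mean(axis=0, keepdims=True)  # average-reference subspace
            sig += design.noise_sd_uv * noise
        data[t] = sig
    return data, rts, acc


def simulate_epochs(
    design: SyntheticDesign, montage: Montage
) -> tuple[list[EpochSet], pd.DataFrame]:
    """Simulate stimulus-locked epochs for every subject and condition.

    Returns one ``EpochSet`` per subject x condition (``stim_epoch_tf``
    frames, ``pre_lock_tf`` of them pre-onset) and a tidy behaviour table
    with columns subject, group, condition, trial, rt_ms, accuracy.
    """
    if montage.n_electrodes != design.n_electrodes:
        raise ValueError("montage size does not match design.n_electrodes")
    templates = _templates(design, montage)
    smooth = _smoothing_matrix(montage, design.spatial_noise_smoothness)
    epoch_sets, rows = [], []
    for g, gname in enumerate(design.group_names):
        for s in range(design.n_subjects_per_group):
            subject = f"{gname}_{s:02d}"
            for c, cname in enumerate(design.condition_names):
                data, rts, acc = _simulate_continuous(
                    design, templates, smooth, g, s, c
                )
                meta = pd.DataFrame(
                    {
                        "trial": np.arange(design.n_trials),
                        "rt_ms": rts,
                        "accuracy": acc,
                    }
                )
                epoch_sets.append(
                    EpochSet(
                        subject=subject,
                        group=gname,
                        condition=cname,
                        lock="stimulus",
                        data=data[:, :, : design.stim_epoch_tf],
                        sampling_rate=design.sampling_rate,
                        pre_lock_tf=design.pre_lock_tf,
                        trial_meta=meta,
                    )
                )
                for t in range(design.n_trials):
                    rows.append(
                        (subject, gname, cname, t, float(rts[t]), bool(acc[t]))
                    )
    behavior = pd.DataFrame(
        rows, columns=["subject", "group", "condition", "trial", "rt_ms", "accuracy"]
    )
    return epoch_sets, behavior


def simulate_response_locked(
    design: SyntheticDesign,
    montage: Montage,
    stimulus_epochs: list[EpochSet] | None = None,
) -> tuple[list[EpochSet], dict[str, int]]:
    """Re-cut the same simulated trials into response-locked epochs.

    Each epoch spans ``resp_epoch_tf`` frames and ends ``resp_end_offset_tf``
    frames before the trial's vocal onset (window relative to picture onset:
    ``[rt_tf - 300, rt_tf - 50)`` at the defaults). Trials whose window would
    start before picture onset are dropped; the returned dict counts drops
    per subject. When ``stimulus_epochs`` is given, RTs are cross-checked
    against its metadata to guarantee the two alignments describe the same
    trials.
    """
    templates = _templates(design, montage)
    smooth = _smoothing_matrix(montage, design.spatial_noise_smoothness)
    fs = design.sampling_rate
    length, end_off = design.resp_epoch_tf, design.resp_end_offset_tf
    lookup = {}
    if stimulus_epochs is not None:
        lookup = {(e.subject, e.condition): e for e in stimulus_epochs}
    epoch_sets, dropped = [], {}
    for g, gname in enumerate(design.group_names):
        for s in range(design.n_subjects_per_group):
            subject = f"{gname}_{s:02d}"
            for c, cname in enumerate(design.condition_names):
                data, rts, acc = _simulate_continuous(
                    design, templates, smooth, g, s, c
                )
                ref = lookup.get((subject, cname))
                if ref is not None and not np.allclose(
                    ref.trial_meta["rt_ms"].to_numpy(), rts
                ):
                    raise ValueError(
                        f"stimulus epochs for {subject}/{cname} came from a "
                        "different design or seed"
                    )
                rt_tf = np.array([_ms_to_tf(rt, fs) for rt in rts])
                start = rt_tf - end_off - length  # relative to picture onset
                keep = start >= 0
                dropped[f"{subject}/{cname}"] = int((~keep).sum())
                idx0 = start[keep] + design.pre_lock_tf  # continuous frame index
                cut = np.stack(
                    [data[t, :, i0 : i0 + length] for t, i0 in zip(np.where(keep)[0], idx0)]
                ) if keep.any() else np.empty((0, montage.n_electrodes, length))
                meta = pd.DataFrame(
                    {
                        "trial": np.where(keep)[0],
                        "rt_ms": rts[keep],
                        "accuracy": acc[keep],
                    }
                )
                epoch_sets.append(
                    EpochSet(
                        subject=subject,
                        group=gname,
                        condition=cname,
                        lock="response",
                        data=cut,
                        sampling_rate=fs,
                        pre_lock_tf=length + end_off,
                        trial_meta=meta,
                    )
                )
    return epoch_sets, dropped


def rt_moments(design: SyntheticDesign, group_idx: int) -> tuple[float, float]:
    """Mean and SD of the truncated RT distribution actually sampled."""
    loc, sd = design.rt_mean_ms[group_idx], design.rt_sd_ms
    a = (design.rt_min_ms - loc) / sd
    b = (design.rt_max_ms - loc) / sd
    m, v = truncnorm.stats(a, b, loc=loc, scale=sd, moments="mv")
    return float(m), float(np.sqrt(v))
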