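"""Sampling-point-wise factorial ANOVA on ERP amplitudes with extent criteria.

At every electrode x time-frame, amplitudes are submitted to a two-way mixed
(split-plot) ANOVA: group is a between-subject factor, condition a
within-subject (repeated) factor with subject as the blocking unit. The
closed-form balanced-design sums of squares are evaluated vectorised over
all points at once, which is what makes a 128 x 300 grid tractable.

Raw point-wise significance is then pruned by the duration/extent rule: an
effect counts only if it persists for at least ``min_consec_tf`` consecutive
frames at an electrode and, throughout that run, the electrode belongs to a
connected set (montage adjacency) of at least ``min_adjacent``
supra-threshold electrodes. No further multiple-testing correction is
applied beyond these criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.stats import f as f_dist

from .containers import Erp
from .montage import Montage

__all__ = ["PointwiseStatMap", "pointwise_anova", "extent_threshold", "significant_runs"]

EFFECTS = ("group", "condition", "interaction")


@dataclass
class PointwiseStatMap:
    """F and p per effect at every electrode x frame, plus extent masks."""

    F: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    df: dict[str, tuple[int, int]]
    alpha: float = 0.01
    criteria: tuple[int, int] = (10, 5)  # (min_consec_tf, min_adjacent)
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        key = next(iter(self.F))
        return self.F[key].shape


def _stack_erps(
    erps: list[Erp], conditions: list[str] | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Arrange per-subject/condition ERPs into (subjects, conditions, E, T)."""
    if conditions is None:
        conditions = sorted({e.condition for e in erps})
    subjects = sorted({e.subject for e in erps})
    by_key = {(e.subject, e.condition): e for e in erps}
    groups = []
    shape = erps[0].data.shape
    y = np.empty((len(subjects), len(conditions)) + shape)
    for i, s in enumerate(subjects):
        missing = [c for c in conditions if (s, c) not in by_key]
        if missing:
            raise ValueError(
                f"subject {s!r} is missing condition(s) {missing}; the design "
                "must be complete"
            )
        cell_groups = {by_key[(s, c)].group for c in conditions}
        if len(cell_groups) != 1:
            raise ValueError(f"subject {s!r} appears under several groups")
        groups.append(cell_groups.pop())
        for j, c in enumerate(conditions):
            e = by_key[(s, c)]
            if e.data.shape != shape:
                raise ValueError("all ERPs must share electrodes x frames shape")
            y[i, j] = e.data
    return y, np.asarray(groups), subjects


def mixed_anova_arrays(
    y: np.ndarray, groups: np.ndarray
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, tuple[int, int]]]:
    """Vectorised split-plot ANOVA on ``y`` (subjects x conditions x ...points).

    Group sizes may differ; each subject must contribute every condition.
    With one condition the model reduces to a one-way between-group ANOVA
    and only the group effect is returned.
    """
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    n_sub, n_cond = y.shape[:2]
    levels, gidx = np.unique(groups, return_inverse=True)
    a = len(levels)
    if a < 2:
        raise ValueError("need at least 2 groups")
    n_g = np.bincount(gidx).astype(float)
    if (n_g < 2).any():
        raise ValueError("every group needs at least 2 subjects")

    m_s = y.mean(axis=1)  # subject means
    grand = m_s.mean(axis=0)
    # group means of subject means (shape a x points)
    m_g = np.stack([m_s[gidx == g].mean(axis=0) for g in range(a)])

    ss_group = n_cond * np.einsum("g,g...->...", n_g, (m_g - grand) ** 2)
    ss_subj = n_cond * ((m_s - m_g[gidx]) ** 2).sum(axis=0)
    df_group = (a - 1, n_sub - a)
    ms_group = ss_group / df_group[0]
    ms_subj = ss_subj / df_group[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_group = np.where(ms_subj > 0, ms_group / np.maximum(ms_subj, 1e-300), 0.0)
    F = {"group": f_group}
    p = {"group": f_dist.sf(f_group, *df_group)}
    df = {"group": df_group}

    if n_cond >= 2:
        m_c = y.mean(axis=0)  # condition means, (conditions x points)
        m_gc = np.stack([y[gidx == g].mean(axis=0) for g in range(a)])  # a x b x pts
        ss_cond = n_sub * ((m_c - grand) ** 2).sum(axis=0)
        inter = m_gc - m_g[:, None] - m_c[None, :] + grand
        ss_int = np.einsum("g,gc...->...", n_g, inter**2)
        resid = y - m_gc[gidx] - m_s[:, None] + m_g[gidx][:, None]
        ss_err = (resid**2).sum(axis=(0, 1))
        df_err = (n_sub - a) * (n_cond - 1)
        ms_err = ss_err / df_err
        for name, ss, df1 in (
            ("condition", ss_cond, n_cond - 1),
            ("interaction", ss_int, (a - 1) * (n_cond - 1)),
        ):
            with np.errstate(divide="ignore", invalid="ignore"):
                fval = np.where(ms_err > 0, (ss / df1) / np.maximum(ms_err, 1e-300), 0.0)
            F[name] = fval
            p[name] = f_dist.sf(fval, df1, df_err)
            df[name] = (df1, df_err)
    return F, p, df


def pointwise_anova(
    erps: list[Erp],
    conditions: list[str] | None = None,
    alpha: float = 0.01,
) -> PointwiseStatMap:
    """Two-way mixed ANOVA (group x condition) at every electrode x frame.

    ``erps`` holds one Erp per subject and condition with ``group`` and
    ``condition`` labels set. Returns F and p maps for the group effect and,
    when two or more conditions are present, the condition and interaction
    effects.
    """
    y, groups, _ = _stack_erps(erps, conditions)
    F, p, df = mixed_anova_arrays(y, groups)
    return PointwiseStatMap(F=F, p=p, df=df, alpha=alpha)


def _spatial_support(sig: np.ndarray, montage: Montage, min_adjacent: int) -> np.ndarray:
    """Per point: is the electrode in a connected supra-threshold set >= size?"""
    n_el, n_tf = sig.shape
    adj = montage.adjacency
    ok = np.zeros_like(sig, dtype=bool)
    for t in range(n_tf):
        on = np.where(sig[:, t])[0]
        if on.size < min_adjacent:
            continue
        sub = adj[on][:, on]
        _, comp = connected_components(sub, directed=False)
        sizes = np.bincount(comp)
        ok[on, t] = sizes[comp] >= min_adjacent
    return ok


def significant_runs(sig_row: np.ndarray):
    """Yield (start, stop) of maximal True runs in a boolean vector."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], sig_row.view(np.int8), [0]])))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)


def extent_threshold(
    stat: PointwiseStatMap | np.ndarray,
    montage: Montage,
    min_consec_tf: int = 10,
    min_adjacent: int = 5,
    alpha: float = 0.01,
    effect: str | None = None,
) -> np.ndarray | dict[str, np.ndarray]:
    """Apply the duration and spatial-extent criteria to point-wise p-values.

    A point survives iff it lies in a run of at least ``min_consec_tf``
    consecutive supra-threshold frames at its electrode and the electrode
    belongs, at every frame of that run, to a connected set of at least
    ``min_adjacent`` supra-threshold electrodes. Passing a
    ``PointwiseStatMap`` thresholds every effect and stores the masks on it.
    """
    if isinstance(stat, PointwiseStatMap):
        effects = [effect] if effect else list(stat.p)
        for name in effects:
            stat.mask[name] = extent_threshold(
                stat.p[name], montage, min_consec_tf, min_adjacent, alpha
            )
        stat.alpha = alpha
        stat.criteria = (min_consec_tf, min_adjacent)
        return stat.mask if effect is None else stat.mask[effect]

    p = np.asarray(stat)
    if p.shape[0] != montage.n_electrodes:
        raise ValueError("p-map electrode count does not match the montage")
    sig = p < alpha
    spatial_ok = _spatial_support(sig, montage, min_adjacent)
    mask = np.zeros_like(sig)
    for e in range(sig.shape[0]):
        for start, stop in significant_runs(sig[e]):
            if stop - start >= min_consec_tf and spatial_ok[e, start:stop].all():
                mask[e, start:stop] = True
    return mask
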