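"""Topographic analysis of variance (tANOVA): per-frame randomization tests.

At every time-frame, each subject's scalp map is normalised to unit GFP so
that only the *shape* of the field counts, and the effect size is the mean
global dissimilarity (DISS) between the factor-level mean maps and the grand
mean map. The null distribution is built by randomization that respects the
design: subject-to-group shuffles for the group effect, within-subject
condition swaps for the condition effect, and sign flips of grand-mean
aligned within-subject difference maps for the interaction. The observed
data count as one permutation, so p is never smaller than 1/(n_perm + 1).

A topographic difference that survives the consecutive-significance
criterion (at least 12 frames, about 24 ms, of p below alpha) indicates a
change in the configuration of the active sources rather than a pure
strength modulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Erp
from .mass_univariate import significant_runs, _stack_erps
from .topo import GFP_EPS

__all__ = ["TanovaResult", "tanova", "tanova_arrays", "consecutive_criterion"]

_CHUNK = 250  # permutations per vectorised block (memory cap)


@dataclass
class TanovaResult:
    """Per-frame p-values and generalized-dissimilarity effect sizes."""

    p: dict[str, np.ndarray]
    effect_size: dict[str, np.ndarray]
    untestable: dict[str, np.ndarray]
    n_permutations: int
    alpha: float
    seed: int
    mask: dict[str, np.ndarray] = field(default_factory=dict)


def _normalize_tf(maps: np.ndarray) -> np.ndarray:
    """Average-reference and unit-GFP normalise maps of shape (..., E, T)."""
    x = maps - maps.mean(axis=-2, keepdims=True)
    g = np.sqrt(np.mean(x**2, axis=-2, keepdims=True))
    return x / np.maximum(g, GFP_EPS)


def _mean_diss_to_grand(level_means: np.ndarray, grand: np.ndarray) -> np.ndarray:
    """Mean DISS of each level-mean map to the grand-mean map, per frame.

    ``level_means``: (..., n_levels, E, T); ``grand``: (..., E, T).
    Maps are re-normalised before the RMS difference, per the DISS
    definition. Returns (..., T).
    """
    ln = _normalize_tf(level_means)
    gn = _normalize_tf(grand)[..., None, :, :]
    diss = np.sqrt(np.mean((ln - gn) ** 2, axis=-2))
    return diss.mean(axis=-2)


def consecutive_criterion(
    p_series: np.ndarray, alpha: float = 0.01, min_consec_tf: int = 12
) -> np.ndarray:
    """Keep frames inside runs of >= ``min_consec_tf`` consecutive p < alpha."""
    sig = np.asarray(p_series) < alpha
    mask = np.zeros_like(sig)
    for start, stop in significant_runs(sig):
        if stop - start >= min_consec_tf:
            mask[start:stop] = True
    return mask


def tanova_arrays(
    y: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.01,
    seed: int = 0,
    effects: tuple[str, ...] = ("group", "condition", "interaction"),
    min_consec_tf: int = 12,
) -> TanovaResult:
    """tANOVA on raw arrays: ``y`` is subjects x conditions x electrodes x TFs."""
    y = np.asarray(y, float)
    if y.ndim != 4:
        raise ValueError("y must be subjects x conditions x electrodes x TFs")
    n_sub, n_cond, n_el, n_tf = y.shape
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    groups = np.asarray(groups)
    levels, gidx = np.unique(groups, return_inverse=True)
    a = len(levels)
    n_g = np.bincount(gidx).astype(float)
    if (n_g < 2).any():
        raise ValueError("every group level needs at least 2 subjects")
    rng = np.random.default_rng(seed)

    x = _normalize_tf(y)  # per subject x condition unit-GFP maps
    p_out, es_out, untestable = {}, {}, {}

    def finish(name, obs, counts, bad):
        p = counts / (n_perm + 1)
        p[bad] = np.nan
        p_out[name] = p
        es_out[name] = obs
        untestable[name] = bad

    if "group" in effects and a >= 2:
        s_maps = x.mean(axis=1)  # subject maps (mean of normalised cond maps)
        grand = s_maps.mean(axis=0)
        obs_levels = np.stack([s_maps[gidx == g].mean(axis=0) for g in range(a)])
        bad = _undefined(obs_levels, grand)
        obs = _mean_diss_to_grand(obs_levels, grand)
        counts = np.ones(n_tf)
        z = s_maps.reshape(n_sub, n_el * n_tf)
        done = 0
        while done < n_perm:
            m = min(_CHUNK, n_perm - done)
            perm_idx = rng.permuted(
                np.tile(np.arange(n_sub), (m, 1)), axis=1
            )
            pg = gidx[perm_idx]  # (m, n_sub) permuted group of each subject
            lv = np.empty((m, a, n_el, n_tf))
            for g in range(a):
                w = (pg == g).astype(float) / n_g[g]
                lv[:, g] = (w @ z).reshape(m, n_el, n_tf)
            stats = _mean_diss_to_grand(lv, np.broadcast_to(grand, (m, n_el, n_tf)))
            counts += (stats >= obs[None, :]).sum(axis=0)
            done += m
        finish("group", obs, counts, bad)

    if "condition" in effects and n_cond >= 2:
        grand = x.mean(axis=(0, 1))
        obs_levels = x.mean(axis=0)  # (n_cond, E, T)
        bad = _undefined(obs_levels, grand)
        obs = _mean_diss_to_grand(obs_levels, grand)
        counts = np.ones(n_tf)
        done = 0
        while done < n_perm:
            m = min(_CHUNK, n_perm - done)
            if n_cond == 2:
                # label swap within subject == sign flip of the difference map
                m_a = x[:, 0].mean(axis=0)
                m_b = x[:, 1].mean(axis=0)
                diff = (x[:, 1] - x[:, 0]).reshape(n_sub, n_el * n_tf)
                f = rng.integers(0, 2, size=(m, n_sub)).astype(float)
                delta = ((f / n_sub) @ diff).reshape(m, n_el, n_tf)
                lv = np.stack([m_a + delta, m_b - delta], axis=1)
            else:
                perm = rng.permuted(
                    np.tile(np.arange(n_cond), (m, n_sub, 1)), axis=2
                )
                sub_idx = np.arange(n_sub)[None, :, None]
                lv = x[sub_idx, perm].mean(axis=1)
            stats = _mean_diss_to_grand(lv, np.broadcast_to(grand, (m, n_el, n_tf)))
            counts += (stats >= obs[None, :]).sum(axis=0)
            done += m
        finish("condition", obs, counts, bad)

    if "interaction" in effects and n_cond == 2 and a >= 2:
        # The interaction asks whether the condition-difference topography
        # differs across groups, so the unit of exchange is the
        # within-subject difference map and the randomization shuffles the
        # subject-to-group assignment of those maps (the grand-mean
        # difference is invariant, which keeps the test exact under the
        # null; within-subject label swaps re-test the condition effect and
        # are badly anticonservative here).
        d = x[:, 0] - x[:, 1]  # within-subject difference maps
        d_bar = d.mean(axis=0)
        obs_levels = np.stack([d[gidx == g].mean(axis=0) for g in range(a)])
        bad = _undefined(obs_levels, d_bar)
        obs = _mean_diss_to_grand(obs_levels, d_bar)
        counts = np.ones(n_tf)
        z = d.reshape(n_sub, n_el * n_tf)
        done = 0
        while done < n_perm:
            m = min(_CHUNK, n_perm - done)
            perm_idx = rng.permuted(np.tile(np.arange(n_sub), (m, 1)), axis=1)
            pg = gidx[perm_idx]
            lv = np.empty((m, a, n_el, n_tf))
            for g in range(a):
                w = (pg == g).astype(float) / n_g[g]
                lv[:, g] = (w @ z).reshape(m, n_el, n_tf)
            stats = _mean_diss_to_grand(lv, np.broadcast_to(d_bar, (m, n_el, n_tf)))
            counts += (stats >= obs[None, :]).sum(axis=0)
            done += m
        finish("interaction", obs, counts, bad)

    result = TanovaResult(
        p=p_out,
        effect_size=es_out,
        untestable=untestable,
        n_permutations=n_perm,
        alpha=alpha,
        seed=seed if isinstance(seed, int) else -1,
    )
    for name, p in p_out.items():
        p_masked = np.where(np.isnan(p), 1.0, p)
        result.mask[name] = consecutive_criterion(p_masked, alpha, min_consec_tf)
    return result


def _undefined(level_means: np.ndarray, grand: np.ndarray) -> np.ndarray:
    """Frames where a level mean or the grand mean has (near-)zero field."""
    g_lv = np.sqrt(np.mean(level_means**2, axis=-2)).min(axis=0)
    g_gr = np.sqrt(np.mean(grand**2, axis=-2))
    return (g_lv <= GFP_EPS) | (g_gr <= GFP_EPS)


def tanova(
    erps: list[Erp],
    n_perm: int = 5000,
    alpha: float = 0.01,
    seed: int = 0,
    effects: tuple[str, ...] = ("group", "condition", "interaction"),
    min_consec_tf: int = 12,
    conditions: list[str] | None = None,
) -> TanovaResult:
    """Run the tANOVA on a list of per-subject, per-condition ERPs.

    Every subject must contribute one Erp per condition with ``group`` set.
    Amplitude information is discarded by GFP normalisation, so the p-series
    is invariant to rescaling any subject's data by a positive factor.
    """
    y, groups, _ = _stack_erps(erps, conditions)
    return tanova_arrays(
        y, groups, n_perm=n_perm, alpha=alpha, seed=seed, effects=effects,
        min_consec_tf=min_consec_tf,
    )
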