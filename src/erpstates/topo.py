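"""Reference-free global measures of the scalp electric field.

All measures operate on average-referenced maps (electrode mean zero).
Conventions:

* **GFP** (global field power) uses the 1/N (population standard deviation)
  convention: ``GFP(t) = sqrt(mean_i u_i(t)^2)``. N vs N-1 changes values, so
  this is fixed package-wide.
* **DISS** (global map dissimilarity) is the RMS difference of the two
  GFP-normalised maps and satisfies ``DISS^2 = 2 (1 - r)`` with r the spatial
  Pearson correlation; it ranges over [0, 2].
* **GEV** (global explained variance) is the fraction of GFP-weighted
  variance explained by assigning template maps to time-frames.

Maps with GFP below ``GFP_EPS`` have no defined topography and are excluded
from normalised statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Erp

__all__ = [
    "GFP_EPS",
    "UNASSIGNED",
    "gfp",
    "gfp_series",
    "dissimilarity",
    "spatial_correlation",
    "normalize_map",
    "gev",
    "tct",
    "TctResult",
    "p1_peak_latency",
]

GFP_EPS = 1e-9  # microvolts; below this the normalised map is undefined
UNASSIGNED = -1  # label for time-frames not explained by any template


def _as_maps(x) -> np.ndarray:
    """Coerce input to a (n_maps, n_electrodes) float array."""
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    return a


def gfp(maps) -> np.ndarray | float:
    """Global field power of one map or a stack of maps.

    GFP is the spatial standard deviation (1/N convention) of the
    average-referenced map; the electrode mean is removed here so the value
    is reference-independent.
    """
    a = _as_maps(maps)
    a = a - a.mean(axis=-1, keepdims=True)
    out = np.sqrt(np.mean(a**2, axis=-1))
    return float(out[0]) if np.isscalar(maps[0]) or np.asarray(maps).ndim == 1 else out


def gfp_series(erp: Erp) -> np.ndarray:
    """Per-frame GFP of an averaged ERP (microvolts)."""
    return gfp(erp.data.T)


def normalize_map(u) -> np.ndarray:
    """Average-reference and scale a map to unit GFP.

    Raises
    ------
    ValueError
        If the map's field strength is below ``GFP_EPS`` (undefined field).
    """
    u = np.asarray(u, dtype=float)
    u = u - u.mean()
    g = np.sqrt(np.mean(u**2))
    if g <= GFP_EPS:
        raise ValueError("undefined field: GFP below epsilon, map has no topography")
    return u / g


def spatial_correlation(u, v) -> float:
    """Pearson correlation of two maps across electrodes (in [-1, 1])."""
    un, vn = normalize_map(u), normalize_map(v)
    return float(np.clip(np.mean(un * vn), -1.0, 1.0))


def dissimilarity(u, v) -> float:
    """Global map dissimilarity in [0, 2]: 0 identical, 2 polarity-inverted.

    ``DISS = sqrt(mean_i (u_i/GFP_u - v_i/GFP_v)^2)`` on average-referenced
    maps; equivalently ``sqrt(2 (1 - r))``.
    """
    un, vn = normalize_map(u), normalize_map(v)
    return float(np.sqrt(np.mean((un - vn) ** 2)))


def gev(
    erp: Erp | np.ndarray,
    templates: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Total and per-template global explained variance of a labelling.

    Parameters
    ----------
    erp : Erp or ndarray (electrodes x TFs)
        Average-referenced data.
    templates : ndarray (n_templates, n_electrodes)
        Unit-GFP template maps.
    labels : int ndarray (n_tfs,)
        Template index per frame, or ``UNASSIGNED`` (-1).

    Returns
    -------
    total : float
        ``sum_t (GFP(t) * r(u_t, T_label(t)))^2 / sum_t GFP(t)^2`` over
        assigned frames; in [0, 1].
    per_map : ndarray (n_templates,)
        Partition of the numerator by label (sums to ``total``).
    """
    data = erp.data if isinstance(erp, Erp) else np.asarray(erp, dtype=float)
    labels = np.asarray(labels)
    templates = np.asarray(templates, dtype=float)
    if labels.shape[0] != data.shape[1]:
        raise ValueError("labels length must match frame count")
    if labels.size and labels.max() >= templates.shape[0]:
        raise ValueError("label refers to a template that does not exist")

    u = data - data.mean(axis=0, keepdims=True)
    g = np.sqrt(np.mean(u**2, axis=0))
    denom = float(np.sum(g**2))
    if denom <= GFP_EPS**2:
        raise ValueError("undefined field: data has no signal (all-zero GFP)")

    per_map = np.zeros(templates.shape[0])
    tnorm = templates - templates.mean(axis=1, keepdims=True)
    tg = np.sqrt(np.mean(tnorm**2, axis=1))
    for k in range(templates.shape[0]):
        sel = (labels == k) & (g > GFP_EPS)
        if not sel.any():
            continue
        r = (u[:, sel] * tnorm[k][:, None]).mean(axis=0) / (g[sel] * tg[k])
        per_map[k] = float(np.sum((g[sel] * r) ** 2)) / denom
    return float(per_map.sum()), per_map


@dataclass
class TctResult:
    """Topographic consistency test output.

    ``p_series`` holds one permutation p-value per frame; ``significant`` is
    the p < alpha mask.
    """

    p_series: np.ndarray
    gfp_observed: np.ndarray
    n_permutations: int
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        return self.p_series < self.alpha


def tct(
    subject_maps: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> TctResult:
    """Topographic consistency test across subjects.

    Tests, frame by frame, whether scalp topographies are consistent across
    subjects rather than random noise. The statistic is the GFP of the
    across-subject mean map; the null is built by independently shuffling the
    electrode assignment within each subject and re-averaging. Consistent
    maps survive averaging (high mean-map GFP); random maps cancel.

    Parameters
    ----------
    subject_maps : ndarray (n_subjects, n_electrodes, n_tfs)
        One average-referenced map series per subject (e.g. subject ERPs).
    n_perm : int
        Number of electrode permutations (>= 500).
    """
    x = np.asarray(subject_maps, dtype=float)
    if x.ndim != 3:
        raise ValueError("subject_maps must be subjects x electrodes x TFs")
    n_sub, n_el, n_tf = x.shape
    if n_sub < 5:
        raise ValueError("topographic consistency test needs at least 5 subjects")
    if n_perm < 500:
        raise ValueError("n_perm must be at least 500")

    rng = np.random.default_rng(seed)
    x = x - x.mean(axis=1, keepdims=True)
    observed = np.sqrt(np.mean(x.mean(axis=0) ** 2, axis=0))

    count_ge = np.ones(n_tf)  # observed counted as one permutation
    for _ in range(n_perm):
        # independent electrode shuffle per subject
        idx = rng.random((n_sub, n_el)).argsort(axis=1)
        perm_mean = np.take_along_axis(x, idx[:, :, None], axis=1).mean(axis=0)
        null_gfp = np.sqrt(np.mean(perm_mean**2, axis=0))
        count_ge += null_gfp >= observed
    p = count_ge / (n_perm + 1)
    return TctResult(p, observed, n_perm, alpha)


def p1_peak_latency(erp: Erp, window_ms: tuple[float, float] = (80.0, 160.0)) -> float:
    """Latency (ms) of the maximal GFP sample inside a window.

    Used to quantify the P1 component peak; ties break toward the earlier
    frame. A maximum on the window edge is still returned (the caller can
    detect it by comparing against the window bounds).
    """
    times = erp.times_ms
    lo, hi = window_ms
    sel = (times >= lo) & (times <= hi)
    if not sel.any():
        raise ValueError("latency window lies outside the epoch")
    g = gfp_series(erp)[sel]
    t_win = times[sel]
    return float(t_win[int(np.argmax(g))])
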