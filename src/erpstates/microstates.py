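"""Microstate analysis of ERPs: TAAHC segmentation and individual back-fitting.

Segmentation compresses a set of grand-average ERPs into a small number of
template topographies. The clustering is temporal atomized and agglomerative
hierarchical clustering (TAAHC): time-frames are first grouped into *atoms*
(maximal contiguous runs of near-identical topography), then the cluster
contributing least global explained variance (GEV) is repeatedly dissolved
and its frames reassigned to the remaining cluster with the highest spatial
correlation, until the requested number of clusters remains. Because these
are ERP (component-locked) data, correlations are signed and no polarity
inversion is applied — unlike spontaneous-EEG microstate analysis.

Post-processing merges clusters whose centroids correlate at or above the
merge criterion (default 0.95) and absorbs label runs shorter than the
minimum duration (default 12 frames, about 24 ms at 512 Hz) into the
neighbouring label with the higher correlation.

Back-fitting labels each frame of an *individual* ERP with the candidate
template of highest correlation inside a fitting window, yielding per
subject x template: presence, GEV and duration — the quantitative surface
on which group and condition statistics are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .containers import Erp
from .mass_univariate import mixed_anova_arrays
from .topo import GFP_EPS, UNASSIGNED

__all__ = [
    "Segmentation",
    "taahc_segment",
    "select_model",
    "FittingResult",
    "fit_templates",
    "compare_fitting",
]


@dataclass
class Segmentation:
    """Shared template maps and the per-dataset frame labelling."""

    templates: np.ndarray  # (k, n_electrodes), unit GFP
    labels: dict[str, np.ndarray]  # per dataset, template index or UNASSIGNED
    total_gev: float
    per_map_gev: np.ndarray
    raw_gev: float  # before merge/duration post-processing
    k: int
    min_duration_tf: int
    merge_correlation: float
    template_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.template_names:
            self.template_names = tuple(
                chr(ord("A") + i) for i in range(self.templates.shape[0])
            )


def _norm_maps(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-reference, return (unit maps, gfp) for columns of (E, T)."""
    u = x - x.mean(axis=0, keepdims=True)
    g = np.sqrt(np.mean(u**2, axis=0))
    un = np.where(g > GFP_EPS, u / np.maximum(g, GFP_EPS), 0.0)
    return un, g


def _centroid(member_maps: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """GFP-weighted mean of unit maps, polarity-aligned to the strongest member."""
    anchor = member_maps[:, np.argmax(weights)]
    signs = np.sign(member_maps.T @ anchor / member_maps.shape[0])
    signs[signs == 0] = 1.0
    c = (member_maps * (weights * signs)[None, :]).sum(axis=1)
    g = np.sqrt(np.mean((c - c.mean()) ** 2))
    if g <= GFP_EPS:
        # degenerate (members cancel); fall back to the anchor map
        return anchor.copy()
    return (c - c.mean()) / g


class _Taahc:
    """Working state of the agglomeration over concatenated datasets."""

    def __init__(
        self, un: np.ndarray, g: np.ndarray, atom_id: np.ndarray, signed: bool = True
    ):
        self.un = un  # (E, T) unit maps
        self.g = g  # (T,) gfp
        self.signed = signed
        self.valid = g > GFP_EPS
        self.denom = float(np.sum(g[self.valid] ** 2))
        ids = [i for i in np.unique(atom_id) if i >= 0]
        self.members: dict[int, np.ndarray] = {
            int(i): np.where(atom_id == i)[0] for i in ids
        }
        self.centroids: dict[int, np.ndarray] = {
            i: _centroid(un[:, m], g[m]) for i, m in self.members.items()
        }
        self.gev: dict[int, float] = {i: self._cluster_gev(i) for i in self.members}

    def _cluster_gev(self, i: int) -> float:
        m = self.members[i]
        r = self.centroids[i] @ self.un[:, m] / self.un.shape[0]
        return float(np.sum((self.g[m] * r) ** 2)) / self.denom

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def dissolve_worst(self) -> None:
        worst = min(self.gev, key=self.gev.get)
        orphan = self.members.pop(worst)
        self.centroids.pop(worst)
        self.gev.pop(worst)
        ids = list(self.members)
        cent = np.stack([self.centroids[i] for i in ids])  # (k, E)
        r = cent @ self.un[:, orphan] / self.un.shape[0]  # (k, n_orphan)
        best = np.argmax(r if self.signed else np.abs(r), axis=0)
        touched = set()
        for j, tf in zip(best, orphan):
            i = ids[j]
            self.members[i] = np.append(self.members[i], tf)
            touched.add(i)
        for i in touched:
            m = self.members[i]
            self.centroids[i] = _centroid(self.un[:, m], self.g[m])
            self.gev[i] = self._cluster_gev(i)

    def snapshot(self) -> tuple[np.ndarray, np.ndarray, float]:
        """(centroids, per-frame cluster index, raw total GEV)."""
        ids = list(self.members)
        cent = np.stack([self.centroids[i] for i in ids])
        lab = np.full(self.un.shape[1], UNASSIGNED, dtype=int)
        for pos, i in enumerate(ids):
            lab[self.members[i]] = pos
        raw = float(sum(self.gev.values()))
        return cent, lab, raw


def _polish_once(
    cent, lab, un, g, denom, valid, signed: bool, max_iter: int = 50
):
    """Alternate assignment and centroid updates; return best config seen."""
    cent, lab = cent.copy(), lab.copy()
    best_gev, _ = _total_gev(un, g, lab, cent, denom)
    best = (best_gev, cent.copy(), lab.copy())
    n_el = un.shape[0]
    for _ in range(max_iter):
        r = cent @ un / n_el
        score = r if signed else np.abs(r)
        new_lab = np.where(valid, np.argmax(score, axis=0), UNASSIGNED)
        if np.array_equal(new_lab, lab):
            break
        lab = new_lab
        for k in range(cent.shape[0]):
            m = np.where(lab == k)[0]
            if m.size:
                cent[k] = _centroid(un[:, m], g[m])
        total, _ = _total_gev(un, g, lab, cent, denom)
        if total > best[0]:
            best = (total, cent.copy(), lab.copy())
    return best


def _refine(
    cent, lab, un, g, denom, valid,
    signed: bool = True, n_restarts: int = 4, restart_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Polish the agglomerative solution, with deterministic random restarts.

    The polish pass (reassign every frame to its best centroid, recompute
    centroids, iterate) is the usual microstate refinement; a few seeded
    random restarts guard against poor greedy local optima. The best-GEV
    configuration wins, so refinement can only improve on the agglomerative
    result.
    """
    k = cent.shape[0]
    best = _polish_once(cent, lab, un, g, denom, valid, signed)
    rng = np.random.default_rng(restart_seed)
    tfs = np.where(valid)[0]

    def try_labels(lab0):
        nonlocal best
        if len(np.unique(lab0[tfs])) < k:
            return
        cent0 = np.stack([
            _centroid(un[:, lab0 == j], g[lab0 == j]) for j in range(k)
        ])
        cand = _polish_once(cent0, lab0, un, g, denom, valid, signed)
        if cand[0] > best[0]:
            best = cand

    # contiguous-split initialisations honour the temporal prior; on small
    # problems every split is tried, which dominates any contiguous labelling
    if k >= 2 and tfs.size >= k:
        from itertools import combinations
        from math import comb

        if comb(tfs.size - 1, k - 1) <= 64:
            cut_sets = combinations(range(1, tfs.size), k - 1)
        else:
            cut_sets = (
                np.sort(rng.choice(np.arange(1, tfs.size), k - 1, replace=False))
                for _ in range(n_restarts)
            )
        for cuts in cut_sets:
            lab0 = np.full(lab.shape, UNASSIGNED)
            pieces = np.split(tfs, list(cuts))
            for j, piece in enumerate(pieces):
                lab0[piece] = j
            try_labels(lab0)

    for _ in range(n_restarts):
        if tfs.size < k:
            break
        lab0 = np.full(lab.shape, UNASSIGNED)
        lab0[tfs] = rng.integers(0, k, tfs.size)
        seed_tfs = rng.choice(tfs, size=k, replace=False)
        lab0[seed_tfs] = np.arange(k)
        try_labels(lab0)
    return best[1], best[2]


def _atomize(un: np.ndarray, valid: np.ndarray, bounds: list[int], corr: float) -> np.ndarray:
    """Assign an atom id per frame; contiguous near-identical maps share one.

    A new atom starts at every dataset boundary, at invalid (zero-field)
    frames, and wherever the correlation with the previous frame drops below
    ``corr``. Invalid frames get id -1.
    """
    n_el, n_tf = un.shape
    ids = np.full(n_tf, -1, dtype=int)
    nxt = 0
    starts = set(bounds)
    for t in range(n_tf):
        if not valid[t]:
            continue
        new = (
            t in starts
            or t == 0
            or not valid[t - 1]
            or ids[t - 1] < 0
            or float(un[:, t] @ un[:, t - 1]) / n_el < corr
        )
        if new:
            ids[t] = nxt
            nxt += 1
        else:
            ids[t] = ids[t - 1]
    return ids


def _merge_templates(cent: np.ndarray, lab: np.ndarray, threshold: float):
    """Union clusters whose centroids correlate >= threshold; relabel."""
    k = cent.shape[0]
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    n_el = cent.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            if float(cent[i] @ cent[j]) / n_el >= threshold:
                parent[find(j)] = find(i)
    roots = sorted({find(i) for i in range(k)})
    remap = {r: pos for pos, r in enumerate(roots)}
    lut = np.array([remap[find(i)] for i in range(k)])
    new_lab = np.where(lab >= 0, lut[np.maximum(lab, 0)], lab)
    new_cent = np.empty((len(roots), cent.shape[1]))
    for r, pos in remap.items():
        group = [i for i in range(k) if find(i) == r]
        # merged centroid: mean of member centroids, sign-aligned to the first
        c = cent[group[0]].copy()
        for i in group[1:]:
            s = np.sign(float(cent[i] @ c))
            c += (s if s else 1.0) * cent[i]
        g = np.sqrt(np.mean((c - c.mean()) ** 2))
        new_cent[pos] = (c - c.mean()) / max(g, GFP_EPS)
    return new_cent, new_lab


def _smooth_short_runs(
    lab: np.ndarray, un: np.ndarray, cent: np.ndarray, min_duration: int
) -> np.ndarray:
    """Absorb labelled runs shorter than min_duration into a neighbour label.

    Works within one dataset. Unassigned frames delimit runs and are never
    relabelled. The absorbing neighbour is the one whose centroid correlates
    better (on average) with the run's maps; repeats until stable.
    """
    lab = lab.copy()
    n_el = un.shape[0]
    for _ in range(lab.size):
        runs = []
        t = 0
        while t < lab.size:
            if lab[t] < 0:
                t += 1
                continue
            t0 = t
            while t < lab.size and lab[t] == lab[t0]:
                t += 1
            runs.append((t0, t))
        short = [
            (t0, t1)
            for t0, t1 in runs
            if t1 - t0 < min_duration
        ]
        # keep runs that cannot be absorbed (no labelled neighbour)
        changed = False
        for t0, t1 in sorted(short, key=lambda r: r[1] - r[0]):
            neighbors = []
            if t0 > 0 and lab[t0 - 1] >= 0:
                neighbors.append(lab[t0 - 1])
            if t1 < lab.size and lab[t1] >= 0:
                neighbors.append(lab[t1])
            neighbors = [n for n in dict.fromkeys(neighbors) if n != lab[t0]]
            if not neighbors:
                continue
            scores = [
                float(np.mean(cent[n] @ un[:, t0:t1]) / n_el) for n in neighbors
            ]
            lab[t0:t1] = neighbors[int(np.argmax(scores))]
            changed = True
            break  # re-derive runs after each absorption
        if not changed:
            break
    return lab


def _total_gev(un, g, lab, cent, denom) -> tuple[float, np.ndarray]:
    per_map = np.zeros(cent.shape[0])
    n_el = un.shape[0]
    for k in range(cent.shape[0]):
        sel = lab == k
        if not sel.any():
            continue
        r = cent[k] @ un[:, sel] / n_el
        per_map[k] = float(np.sum((g[sel] * r) ** 2)) / denom
    return float(per_map.sum()), per_map


def taahc_segment(
    erps: list[Erp],
    k_range: range | list[int],
    min_duration_tf: int = 12,
    merge_correlation: float = 0.95,
    atom_correlation: float = 0.95,
    dataset_keys: list[str] | None = None,
    polarity: str = "signed",
    n_restarts: int = 4,
) -> list[Segmentation]:
    """TAAHC segmentation of one or more (grand-average) ERPs.

    All datasets are segmented jointly so the template set is shared across
    groups and conditions; atoms never span dataset boundaries. Returns one
    Segmentation per requested k, ascending.

    ``polarity="signed"`` (the ERP convention) never inverts a map when
    assigning frames; ``polarity="ignore"`` clusters on absolute
    correlation, which matches the sign-agnostic GEV objective and is the
    spontaneous-EEG convention. ``n_restarts`` deterministic random
    restarts of the polish pass guard against greedy local optima.
    """
    if polarity not in ("signed", "ignore"):
        raise ValueError("polarity must be 'signed' or 'ignore'")
    signed = polarity == "signed"
    datas = [e.data if isinstance(e, Erp) else np.asarray(e, float) for e in erps]
    n_el = datas[0].shape[0]
    if any(d.shape[0] != n_el for d in datas):
        raise ValueError("all datasets must share the montage")
    if dataset_keys is None:
        dataset_keys = [getattr(e, "subject", "") or f"dataset{i}" for i, e in enumerate(erps)]
        if len(set(dataset_keys)) != len(dataset_keys):
            dataset_keys = [f"dataset{i}" for i in range(len(erps))]

    x = np.concatenate(datas, axis=1)
    bounds = list(np.cumsum([0] + [d.shape[1] for d in datas]))[:-1]
    splits = np.cumsum([d.shape[1] for d in datas])[:-1]
    un, g = _norm_maps(x)
    valid = g > GFP_EPS
    atom_id = _atomize(un, valid, bounds, atom_correlation)
    state = _Taahc(un, g, atom_id, signed=signed)

    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 1:
        raise ValueError("k must be >= 1")
    if ks[0] > state.n_clusters:
        raise ValueError(
            f"k={ks[0]} exceeds the {state.n_clusters} atoms available"
        )
    if ks[-1] > state.n_clusters:
        import warnings

        warnings.warn(
            f"only {state.n_clusters} atoms; skipping k > {state.n_clusters}",
            stacklevel=2,
        )
        ks = [k for k in ks if k <= state.n_clusters]

    out: list[Segmentation] = []
    want = set(ks)
    while True:
        if state.n_clusters in want:
            cent, lab, raw = state.snapshot()
            cent, lab = _refine(cent, lab, un, g, state.denom, valid,
                                signed=signed, n_restarts=n_restarts)
            out.append(
                _postprocess(
                    cent, lab, un, g, state.denom, splits, dataset_keys,
                    state.n_clusters, min_duration_tf, merge_correlation,
                )
            )
            want.discard(state.n_clusters)
        if not want or state.n_clusters <= 1:
            break
        state.dissolve_worst()
    out.sort(key=lambda s: s.k)
    return out


def _postprocess(
    cent, lab, un, g, denom, splits, dataset_keys, k, min_duration_tf, merge_corr
) -> Segmentation:
    raw, _ = _total_gev(un, g, lab, cent, denom)
    cent, lab = _merge_templates(cent, lab, merge_corr)
    pieces = np.split(lab, splits)
    un_pieces = np.split(un, splits, axis=1)
    smoothed = [
        _smooth_short_runs(p, u, cent, min_duration_tf)
        for p, u in zip(pieces, un_pieces)
    ]
    lab2 = np.concatenate(smoothed)
    total, per_map = _total_gev(un, g, lab2, cent, denom)
    return Segmentation(
        templates=cent,
        labels={key: l for key, l in zip(dataset_keys, smoothed)},
        total_gev=total,
        per_map_gev=per_map,
        raw_gev=raw,
        k=k,
        min_duration_tf=min_duration_tf,
        merge_correlation=merge_corr,
    )


def select_model(
    segmentations: list[Segmentation], gev_threshold: float = 0.95
) -> tuple[Segmentation, pd.DataFrame]:
    """Pick the smallest k whose total GEV reaches the threshold.

    Returns the chosen segmentation and the full GEV-versus-k curve. If no k
    reaches the threshold the largest-k segmentation is returned with a
    warning.
    """
    segs = sorted(segmentations, key=lambda s: s.k)
    curve = pd.DataFrame(
        {"k": [s.k for s in segs], "gev": [s.total_gev for s in segs],
         "raw_gev": [s.raw_gev for s in segs]}
    )
    for s in segs:
        if s.total_gev >= gev_threshold:
            return s, curve
    import warnings

    warnings.warn(
        f"no model reached GEV {gev_threshold:.2f} "
        f"(max {segs[-1].total_gev:.3f} at k={segs[-1].k}); returning max k",
        stacklevel=2,
    )
    return segs[-1], curve


# ---------------------------------------------------------------------------
# back-fitting


@dataclass
class FittingResult:
    """Per subject x window x template presence/GEV/duration table."""

    table: pd.DataFrame
    labels: np.ndarray  # per-frame label inside the window (candidate index)
    window_tf: tuple[int, int]
    candidates: tuple[str, ...]


def fit_templates(
    individual: Erp,
    templates: np.ndarray,
    template_names: tuple[str, ...],
    candidates: list[str],
    window_tf: tuple[int, int],
    min_presence_tf: int = 12,
    min_duration_tf: int = 12,
    sampling_rate: float | None = None,
) -> FittingResult:
    """Back-fit candidate template maps into one individual ERP window.

    Each frame in the window is labelled with the candidate of highest
    signed spatial correlation (no polarity inversion); runs shorter than
    ``min_duration_tf`` are absorbed as in segmentation. A map is *present*
    when its total assigned duration reaches ``min_presence_tf`` frames.
    GEV is computed within the window only.
    """
    if not candidates:
        raise ValueError("candidate template list is empty")
    data = individual.data if isinstance(individual, Erp) else np.asarray(individual)
    fs = sampling_rate or (individual.sampling_rate if isinstance(individual, Erp) else None)
    if fs is None:
        raise ValueError("sampling_rate required when fitting a bare array")
    lo, hi = window_tf
    if not (0 <= lo < hi <= data.shape[1]):
        raise ValueError(f"fitting window {window_tf} outside the ERP")
    name_to_idx = {n: i for i, n in enumerate(template_names)}
    missing = [c for c in candidates if c not in name_to_idx]
    if missing:
        raise ValueError(f"unknown template name(s): {missing}")
    cand_idx = [name_to_idx[c] for c in candidates]
    cand_maps = np.asarray(templates, float)[cand_idx]

    un, g = _norm_maps(data[:, lo:hi])
    valid = g > GFP_EPS
    n_el = un.shape[0]
    r = cand_maps @ un / n_el  # (n_cand, n_win) signed correlations
    lab = np.argmax(r, axis=0)
    # temporal-continuity tie-break: equal correlations keep the previous label
    best = r[lab, np.arange(lab.size)]
    for t in range(1, lab.size):
        prev = lab[t - 1]
        if prev != lab[t] and np.isclose(r[prev, t], best[t]):
            lab[t] = prev
    lab[~valid] = UNASSIGNED
    lab = _smooth_short_runs(lab, un, cand_maps, min_duration_tf)

    denom = float(np.sum(g[valid] ** 2))
    step_ms = 1000.0 / fs
    rows = []
    for ci, cname in enumerate(candidates):
        sel = lab == ci
        n_tf = int(sel.sum())
        gev_c = 0.0
        if n_tf and denom > 0:
            rr = cand_maps[ci] @ un[:, sel] / n_el
            gev_c = float(np.sum((g[sel] * rr) ** 2)) / denom
        onset = np.flatnonzero(sel)
        rows.append(
            {
                "subject": getattr(individual, "subject", ""),
                "group": getattr(individual, "group", ""),
                "condition": getattr(individual, "condition", ""),
                "template": cname,
                "presence": n_tf >= min_presence_tf,
                "gev": gev_c,
                "n_tf": n_tf,
                "duration_ms": n_tf * step_ms,
                "onset_ms": (lo + int(onset[0])) * step_ms if onset.size else np.nan,
            }
        )
    return FittingResult(
        table=pd.DataFrame(rows),
        labels=lab,
        window_tf=(lo, hi),
        candidates=tuple(candidates),
    )


def compare_fitting(
    table: pd.DataFrame,
    measures: tuple[str, ...] = ("gev", "duration_ms"),
    covariate: pd.Series | None = None,
) -> dict:
    """Group x condition statistics on back-fitting measures, per template.

    For each template and measure, runs the two-way mixed ANOVA (group
    between subjects, condition within). Returns a dict with an ``anova``
    tidy table, per-template ``presence`` contingency tables
    (group x condition counts), and, when ``covariate`` is given (indexed by
    subject), the Pearson correlation of per-subject mean GEV with it.
    """
    required = {"subject", "group", "condition", "template"}
    if not required <= set(table.columns):
        raise ValueError(f"fitting table must have columns {sorted(required)}")
    conditions = sorted(table["condition"].unique())
    rows = []
    presence = {}
    for tmpl, sub in table.groupby("template"):
        pivot_groups = sub.drop_duplicates("subject").set_index("subject")["group"]
        for measure in measures:
            wide = sub.pivot_table(
                index="subject", columns="condition", values=measure, aggfunc="mean"
            ).reindex(columns=conditions)
            if wide.isna().any().any():
                raise ValueError(
                    f"degenerate cells for template {tmpl!r}/{measure}: "
                    "some subjects lack a condition"
                )
            groups = pivot_groups.reindex(wide.index).to_numpy()
            cell_counts = pd.Series(groups).value_counts()
            if (cell_counts < 2).any():
                raise ValueError(f"template {tmpl!r}: a group has < 2 subjects")
            y = wide.to_numpy()[:, :, None]  # subjects x conditions x 1 point
            if np.allclose(y, y.mean()):
                # identical values everywhere: no variance to explain
                for eff in ("group",) + (("condition", "interaction") if len(conditions) > 1 else ()):
                    rows.append(
                        {"template": tmpl, "measure": measure, "effect": eff,
                         "F": 0.0, "p": 1.0, "df1": np.nan, "df2": np.nan}
                    )
                continue
            F, p, df = mixed_anova_arrays(y, groups)
            for eff in F:
                rows.append(
                    {
                        "template": tmpl,
                        "measure": measure,
                        "effect": eff,
                        "F": float(F[eff][0]),
                        "p": float(p[eff][0]),
                        "df1": df[eff][0],
                        "df2": df[eff][1],
                    }
                )
        if "presence" in sub.columns:
            presence[tmpl] = sub.pivot_table(
                index="group", columns="condition", values="presence", aggfunc="sum"
            )
    out = {"anova": pd.DataFrame(rows), "presence": presence}
    if covariate is not None and "gev" in table.columns:
        per_subj = table.groupby("subject")["gev"].mean()
        joined = pd.concat([per_subj, covariate.rename("cov")], axis=1).dropna()
        r, p = pearsonr(joined["gev"], joined["cov"])
        out["covariate"] = {"r": float(r), "p": float(p), "n": len(joined)}
    return out
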