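"""Point-wise mixed ANOVA and the duration/extent significance criteria."""

import numpy as np
import pytest
from scipy.stats import ttest_ind

from erpstates.containers import Erp
from erpstates.mass_univariate import (
    extent_threshold,
    mixed_anova_arrays,
    pointwise_anova,
)


def _make_erps(y, groups, conditions=("c1", "c2")):
    erps = []
    for s in range(y.shape[0]):
        for c, cname in enumerate(conditions):
            erps.append(
                Erp(y[s, c], 512.0, 0, subject=f"s{s:02d}", group=groups[s],
                    condition=cname)
            )
    return erps


class TestMixedAnova:
    def test_two_group_one_condition_equals_squared_t(self, rng):
        y = rng.standard_normal((16, 1, 3, 4))
        groups = np.repeat(["a", "b"], 8)
        F, p, df = mixed_anova_arrays(y, groups)
        t, pt = ttest_ind(y[:8, 0], y[8:, 0], axis=0)
        assert np.allclose(F["group"], t**2, atol=1e-9)
        assert np.allclose(p["group"], pt, atol=1e-12)

    def test_matches_pingouin_mixed_anova(self, rng):
        import pandas as pd
        import pingouin as pg

        y = rng.standard_normal((12, 2, 1, 1))
        groups = np.repeat(["g1", "g2", "g3"], 4)
        F, p, df = mixed_anova_arrays(y, groups)
        long = pd.DataFrame(
            {
                "y": y[:, :, 0, 0].ravel(),
                "subject": np.repeat(np.arange(12), 2),
                "cond": np.tile(["c1", "c2"], 12),
                "group": np.repeat(groups, 2),
            }
        )
        ref = pg.mixed_anova(long, dv="y", within="cond", subject="subject",
                             between="group")
        ref = ref.set_index("Source")
        assert F["group"][0, 0] == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert F["condition"][0, 0] == pytest.approx(ref.loc["cond", "F"], rel=1e-9)
        assert F["interaction"][0, 0] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )

    def test_null_p_values_are_uniform(self, rng):
        y = rng.standard_normal((20, 2, 8, 40))
        groups = np.repeat(["a", "b", "c", "d"], 5)
        _, p, _ = mixed_anova_arrays(y, groups)
        for eff in ("group", "condition", "interaction"):
            frac = float((p[eff] < 0.01).mean())
            # 320 points, 95% binomial band around 0.01
            assert frac < 0.01 + 2.5 * np.sqrt(0.01 * 0.99 / 320)

    def test_planted_effect_maximises_f_inside_region(self, rng):
        y = 0.3 * rng.standard_normal((16, 2, 16, 60))
        groups = np.repeat(["a", "b"], 8)
        y[8:, :, 4:10, 20:50] += 5.0  # group effect on 6 electrodes x 30 TFs
        F, _, _ = mixed_anova_arrays(y, groups)
        e, t = np.unravel_index(np.argmax(F["group"]), F["group"].shape)
        assert 4 <= e < 10 and 20 <= t < 50

    def test_incomplete_design_is_an_error(self, rng):
        y = rng.standard_normal((8, 2, 2, 2))
        groups = np.repeat(["a", "b"], 4)
        erps = _make_erps(y, groups)[:-1]  # drop one condition cell
        with pytest.raises(ValueError, match="missing condition"):
            pointwise_anova(erps)


class TestExtentThreshold:
    def _pmap(self, montage, cluster, tfs, n_tf=60):
        p = np.ones((montage.n_electrodes, n_tf))
        p[np.asarray(cluster)[:, None], np.asarray(tfs)[None, :]] = 1e-4
        return p

    def _connected_cluster(self, montage, size):
        seed_e = 0
        grown = [seed_e]
        frontier = list(montage.neighbors(seed_e))
        while len(grown) < size and frontier:
            e = frontier.pop(0)
            if e not in grown:
                grown.append(e)
                frontier.extend(montage.neighbors(e))
        return grown[:size]

    def test_run_of_9_frames_is_removed(self, montage32):
        cluster = self._connected_cluster(montage32, 6)
        p = self._pmap(montage32, cluster, range(20, 29))
        mask = extent_threshold(p, montage32, 10, 5, 0.01)
        assert mask.sum() == 0

    def test_run_of_12_frames_on_5_adjacent_is_retained(self, montage32):
        cluster = self._connected_cluster(montage32, 5)
        p = self._pmap(montage32, cluster, range(20, 32))
        mask = extent_threshold(p, montage32, 10, 5, 0.01)
        assert mask.sum() == 5 * 12

    def test_four_adjacent_plus_distant_is_removed(self, montage32):
        cluster = self._connected_cluster(montage32, 4)
        # find an electrode not adjacent to any cluster member
        adj = montage32.adjacency.toarray()
        distant = next(
            e for e in range(montage32.n_electrodes)
            if e not in cluster and not adj[e, cluster].any()
        )
        p = self._pmap(montage32, cluster + [distant], range(20, 32))
        mask = extent_threshold(p, montage32, 10, 5, 0.01)
        assert mask.sum() == 0

    def test_matches_connected_component_oracle_on_random_masks(self, montage16, rng):
        import networkx as nx

        graph = nx.from_scipy_sparse_array(montage16.adjacency)
        for _ in range(10):
            p = rng.uniform(0, 0.03, (16, 40))
            mask = extent_threshold(p, montage16, min_consec_tf=3,
                                    min_adjacent=3, alpha=0.01)
            sig = p < 0.01
            # oracle: recompute eligibility per point with networkx components
            spatial = np.zeros_like(sig)
            for t in range(40):
                on = set(np.flatnonzero(sig[:, t]))
                for comp in nx.connected_components(graph.subgraph(on)):
                    if len(comp) >= 3:
                        for e in comp:
                            spatial[e, t] = True
            expect = np.zeros_like(sig)
            for e in range(16):
                run = 0
                for t in range(41):
                    inside = t < 40 and sig[e, t]
                    if inside:
                        run += 1
                    elif run:
                        if run >= 3 and spatial[e, t - run:t].all():
                            expect[e, t - run:t] = True
                        run = 0
            assert np.array_equal(mask, expect)

    def test_mask_shrinks_with_stricter_criteria(self, montage16, rng):
        p = rng.uniform(0, 0.05, (16, 50))
        base = extent_threshold(p, montage16, 3, 2, 0.05)
        assert extent_threshold(p, montage16, 5, 2, 0.05).sum() <= base.sum()
        assert extent_threshold(p, montage16, 3, 4, 0.05).sum() <= base.sum()
        assert extent_threshold(p, montage16, 3, 2, 0.01).sum() <= base.sum()

    def test_familywise_rate_under_null(self, montage16, rng):
        # with the study criteria (alpha .01, 10 TFs, 5 electrodes), random
        # noise almost never produces a surviving cluster
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            y = rng.standard_normal((12, 1, 16, 80))
            groups = np.repeat(["a", "b"], 6)
            _, p, _ = mixed_anova_arrays(y, groups)
            mask = extent_threshold(p["group"], montage16, 10, 5, 0.01)
            hits += bool(mask.any())
        assert hits / n_rep < 0.05
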