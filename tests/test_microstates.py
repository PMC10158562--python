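"""TAAHC segmentation, model selection, back-fitting and fitting statistics."""

import numpy as np
import pandas as pd
import pytest

from erpstates.containers import Erp
from erpstates.microstates import (
    _centroid,
    _norm_maps,
    _total_gev,
    compare_fitting,
    fit_templates,
    select_model,
    taahc_segment,
)


def _erp(data, fs=512.0, **kw):
    return Erp(np.asarray(data, float), fs, 0, **kw)


def _planted_sequence(templates, run_lengths, amps=None, rng=None, noise=0.0):
    labels = np.concatenate(
        [np.full(n, i) for i, n in enumerate(run_lengths)]
    ) % templates.shape[0]
    labels = np.concatenate([np.full(n, i % templates.shape[0])
                             for i, n in enumerate(run_lengths)])
    amp = 2.0 if amps is None else amps
    data = (templates[labels] * amp).T
    if noise > 0:
        e = rng.standard_normal(data.shape)
        e -= e.mean(axis=0, keepdims=True)
        data = data + noise * e
    return data, labels


class TestTaahc:
    def test_noise_free_recovery_is_exact(self, templates4):
        data, labels = _planted_sequence(templates4, [25, 25, 25, 25])
        segs = taahc_segment([_erp(data)], k_range=[4], min_duration_tf=12,
                             merge_correlation=0.999)
        seg = segs[0]
        assert seg.total_gev == pytest.approx(1.0, abs=1e-9)
        got = list(seg.labels.values())[0]
        # up to label permutation the runs must match exactly
        corr = seg.templates @ templates4.T / 16
        mapping = np.argmax(corr, axis=1)
        assert sorted(mapping) == [0, 1, 2, 3]
        assert np.array_equal(mapping[got], labels)
        assert all(
            abs(corr[i, mapping[i]]) >= 0.999 for i in range(4)
        )

    def test_snr10db_recovery_over_20_runs(self, montage16):
        from erpstates.synth import make_template_maps

        rng = np.random.default_rng(77)
        ok = 0
        for run in range(20):
            t = make_template_maps(4, montage16, 0.5, seed=200 + run)
            sig, _ = _planted_sequence(t, [25, 25, 25, 25])
            noise = rng.standard_normal(sig.shape)
            noise -= noise.mean(axis=0, keepdims=True)
            scale = np.sqrt(np.mean(sig**2) / (10.0 * np.mean(noise**2)))
            data = sig + scale * noise
            segs = taahc_segment([_erp(data)], k_range=[4], min_duration_tf=12,
                                 merge_correlation=0.95)
            corr = np.abs(segs[0].templates @ t.T / 16).max(axis=0)
            ok += bool((corr >= 0.95).all())
        assert ok == 20

    def test_gev_non_decreasing_in_k_before_merge(self, templates4, rng):
        data, _ = _planted_sequence(
            templates4, [20, 20, 20, 20], rng=rng, noise=0.8
        )
        segs = taahc_segment([_erp(data)], k_range=range(2, 8),
                             min_duration_tf=1, merge_correlation=0.9999)
        raw = [s.raw_gev for s in segs]
        assert all(b >= a - 1e-9 for a, b in zip(raw, raw[1:]))

    def test_labels_invariant_to_amplitude_rescaling(self, templates4, rng):
        data, _ = _planted_sequence(
            templates4, [20, 20, 20, 20], rng=rng, noise=0.5
        )
        segs1 = taahc_segment([_erp(data)], k_range=[4])
        segs2 = taahc_segment([_erp(data * 5.0)], k_range=[4])
        l1 = list(segs1[0].labels.values())[0]
        l2 = list(segs2[0].labels.values())[0]
        # identical partition up to a permutation of template ids
        mapping = {}
        for a, b in zip(l1, l2):
            assert mapping.setdefault(a, b) == b
        assert len(set(mapping.values())) == len(mapping)

    def test_no_run_shorter_than_min_duration_after_smoothing(
        self, templates4, rng
    ):
        data, _ = _planted_sequence(
            templates4, [18, 5, 30, 4, 25, 18], rng=rng, noise=0.6
        )
        segs = taahc_segment([_erp(data)], k_range=[3, 4], min_duration_tf=12)
        for seg in segs:
            for lab in seg.labels.values():
                run = 0
                prev = None
                for v in list(lab) + [None]:
                    if v == prev and v is not None:
                        run += 1
                    else:
                        if prev is not None and prev >= 0:
                            assert run >= min(seg.min_duration_tf, len(lab))
                        run = 1
                        prev = v

    def test_tiny_instance_reaches_exhaustive_contiguous_optimum(self, rng):
        # 4 electrodes x 8 frames: enumerate every contiguous 2-labelling
        # with the same centroid rule and require TAAHC >= the best of them
        for _ in range(20):
            data = rng.standard_normal((4, 8)) * rng.uniform(0.5, 2.0, (1, 8))
            un, g = _norm_maps(data)
            denom = float(np.sum(g**2))
            best = -1.0
            for b in range(1, 8):
                lab = np.array([0] * b + [1] * (8 - b))
                cent = np.stack(
                    [_centroid(un[:, lab == k], g[lab == k]) for k in (0, 1)]
                )
                tot, _ = _total_gev(un, g, lab, cent, denom)
                best = max(best, tot)
            segs = taahc_segment(
                [_erp(data)], k_range=[2], min_duration_tf=1,
                merge_correlation=0.99999, atom_correlation=2.0,
                polarity="ignore",
            )
            assert segs[0].total_gev >= best - 1e-9

    def test_k_larger_than_atom_count_errors(self, templates4):
        data, _ = _planted_sequence(templates4, [25, 25, 25, 25])
        with pytest.raises(ValueError, match="atoms"):
            taahc_segment([_erp(data)], k_range=[50])

    def test_joint_segmentation_shares_templates(self, templates4, rng):
        d1, _ = _planted_sequence(templates4[:2], [30, 30], rng=rng, noise=0.3)
        d2, _ = _planted_sequence(templates4[2:], [30, 30], rng=rng, noise=0.3)
        segs = taahc_segment([_erp(d1), _erp(d2)], k_range=[4],
                             dataset_keys=["a", "b"])
        seg = segs[0]
        assert set(seg.labels) == {"a", "b"}
        assert seg.templates.shape[0] == 4


class TestSelectModel:
    def test_threshold_rule(self, templates4):
        segs = []
        for k, gevv in zip([1, 2, 3, 4], [0.80, 0.93, 0.96, 0.97]):
            segs.append(
                type("S", (), dict(k=k, total_gev=gevv, raw_gev=gevv))()
            )
        best, curve = select_model(segs, 0.95)
        assert best.k == 3
        assert list(curve["k"]) == [1, 2, 3, 4]

    def test_unreachable_threshold_warns_and_returns_max_k(self):
        segs = [
            type("S", (), dict(k=k, total_gev=g, raw_gev=g))()
            for k, g in zip([1, 2], [0.90, 0.97])
        ]
        with pytest.warns(UserWarning, match="no model reached"):
            best, _ = select_model(segs, 0.99)
        assert best.k == 2

    def test_planted_k_selected_on_grand_average(self, montage16):
        # per-subject SNR 10 dB; segmentation runs on the subject average
        from erpstates.synth import make_template_maps

        rng = np.random.default_rng(31)
        chosen = []
        for run in range(20):
            t = make_template_maps(4, montage16, 0.5, seed=300 + run)
            sig, _ = _planted_sequence(t, [25, 25, 25, 25])
            avg = np.zeros_like(sig)
            n_sub = 10
            for _s in range(n_sub):
                e = rng.standard_normal(sig.shape)
                e -= e.mean(axis=0, keepdims=True)
                scale = np.sqrt(np.mean(sig**2) / (10.0 * np.mean(e**2)))
                avg += sig + scale * e
            avg /= n_sub
            segs = taahc_segment([_erp(avg)], k_range=range(2, 9),
                                 min_duration_tf=12, merge_correlation=0.95)
            best, _ = select_model(segs, 0.95)
            chosen.append(best.templates.shape[0])
        assert sum(c == 4 for c in chosen) >= 18


class TestFitTemplates:
    def test_noise_free_two_state_fitting(self, templates4):
        data = np.concatenate(
            [np.tile(templates4[0][:, None], 50), np.tile(templates4[1][:, None], 50)],
            axis=1,
        ) * 2.0
        erp = _erp(data)
        res = fit_templates(erp, templates4, ("A", "B", "C", "D"),
                            candidates=["A", "B"], window_tf=(0, 100))
        t = res.table.set_index("template")
        assert bool(t.loc["A", "presence"]) and bool(t.loc["B", "presence"])
        assert t.loc["A", "n_tf"] == 50 and t.loc["B", "n_tf"] == 50
        assert t.loc["A", "onset_ms"] == 0.0
        assert t.loc["B", "onset_ms"] == pytest.approx(50 * 1000 / 512)

    def test_single_candidate_gev_matches_gev_operation(self, templates4, rng):
        from erpstates.topo import gev

        data = rng.standard_normal((16, 80)) + 1.5 * templates4[0][:, None]
        erp = _erp(data)
        res = fit_templates(erp, templates4, ("A", "B", "C", "D"),
                            candidates=["A"], window_tf=(0, 80),
                            min_duration_tf=1)
        labels = np.zeros(80, int)
        total, _ = gev(erp, templates4, labels)
        assert res.table.iloc[0]["gev"] == pytest.approx(total, abs=1e-12)

    def test_pure_noise_rarely_reaches_presence(self, templates4, rng):
        present = 0
        for _ in range(100):
            data = rng.standard_normal((16, 40))
            res = fit_templates(_erp(data), templates4, ("A", "B", "C", "D"),
                                candidates=["A", "B"], window_tf=(0, 40),
                                min_presence_tf=24, min_duration_tf=1)
            present += int(res.table["presence"].any())
        # a 40-frame noise window seldom gives one map >= 24 frames
        assert present <= 35

    def test_self_consistency_with_segmentation_labels(self, templates4, rng):
        data, _ = _planted_sequence(templates4, [25, 25, 25, 25],
                                    rng=rng, noise=0.3)
        segs = taahc_segment([_erp(data)], k_range=[4], min_duration_tf=12)
        seg = segs[0]
        res = fit_templates(_erp(data), seg.templates, seg.template_names,
                            candidates=list(seg.template_names),
                            window_tf=(0, 100), min_duration_tf=12)
        ref = list(seg.labels.values())[0]
        agree = float((res.labels == ref).mean())
        assert agree >= 0.95

    def test_empty_candidates_error(self, templates4):
        with pytest.raises(ValueError, match="empty"):
            fit_templates(_erp(np.ones((16, 10))), templates4,
                          ("A", "B", "C", "D"), [], (0, 10))


class TestCompareFitting:
    def _table(self, gev_by_group, n=8, rng=None):
        rows = []
        for g, (gname, mean) in enumerate(gev_by_group.items()):
            for s in range(n):
                for c in ("c1", "c2"):
                    noise = 0.0 if rng is None else 0.01 * rng.standard_normal()
                    rows.append(
                        {"subject": f"{gname}{s}", "group": gname,
                         "condition": c, "template": "A", "window": "w",
                         "presence": True, "gev": mean + noise,
                         "duration_ms": 100.0 + 1000 * mean + 10 * noise}
                    )
        return pd.DataFrame(rows)

    def test_identical_values_give_f_zero_p_one(self):
        table = self._table({"g1": 0.5, "g2": 0.5})
        res = compare_fitting(table)
        assert (res["anova"]["F"] == 0.0).all()
        assert (res["anova"]["p"] == 1.0).all()

    def test_planted_group_difference_detected(self, rng):
        table = self._table({"g1": 0.50, "g2": 0.56}, rng=rng)
        res = compare_fitting(table)
        a = res["anova"].set_index(["measure", "effect"])
        assert a.loc[("gev", "group"), "p"] < 0.01
        assert a.loc[("duration_ms", "group"), "p"] < 0.01

    def test_covariate_correlation_recovered(self, rng):
        table = self._table({"g1": 0.5, "g2": 0.5}, rng=rng)
        subjects = table["subject"].unique()
        age = pd.Series(np.arange(len(subjects), dtype=float), index=subjects)
        # make gev decrease with age
        table = table.merge(age.rename("age"), left_on="subject",
                            right_index=True)
        table["gev"] = 0.8 - 0.01 * table["age"] + 0.005 * rng.standard_normal(len(table))
        res = compare_fitting(table, covariate=age)
        assert res["covariate"]["r"] < -0.5
        assert res["covariate"]["p"] < 0.05

    def test_degenerate_cells_are_reported(self):
        table = self._table({"g1": 0.5, "g2": 0.6})
        table = table[~((table.subject == "g10") & (table.condition == "c2"))]
        with pytest.raises(ValueError, match="lack a condition"):
            compare_fitting(table)
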