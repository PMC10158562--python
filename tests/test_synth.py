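"""Synthetic generator: planted structure, determinism, behaviour models."""

import itertools

import numpy as np
import pytest

from erpstates import synth
from erpstates.topo import spatial_correlation
from erpstates.containers import Erp
from erpstates.topo import gfp_series


class TestTemplateMaps:
    def test_single_map_is_normalized(self, montage32):
        t = synth.make_template_maps(1, montage32, seed=0)
        assert t.shape == (1, 32)
        assert abs(t[0].mean()) < 1e-10
        assert np.sqrt(np.mean(t[0] ** 2)) == pytest.approx(1.0, abs=1e-10)

    def test_seeded_determinism(self, montage32):
        a = synth.make_template_maps(4, montage32, 0.5, seed=7)
        b = synth.make_template_maps(4, montage32, 0.5, seed=7)
        assert np.array_equal(a, b)
        c = synth.make_template_maps(4, montage32, 0.5, seed=8)
        assert not np.array_equal(a, c)

    def test_pairwise_separation_holds(self, montage32):
        maps = synth.make_template_maps(4, montage32, 0.5, seed=7)
        worst = max(
            abs(spatial_correlation(u, v))
            for u, v in itertools.combinations(maps, 2)
        )
        assert worst <= 0.5

    def test_unachievable_separation_errors(self, montage16):
        with pytest.raises(RuntimeError, match="could not place"):
            synth.make_template_maps(
                30, montage16, 0.05, seed=0, max_attempts_per_map=20
            )


def _noise_free(design):
    return synth.SyntheticDesign(
        **{**_asdict(design), "noise_sd_uv": 0.0}
    )


def _asdict(design):
    import dataclasses

    d = dataclasses.asdict(design)
    d["state_sequence"] = tuple(
        synth.StateSpec(**s) for s in d["state_sequence"]
    )
    d.pop("template_maps")
    return d


class TestSimulateEpochs:
    def test_noise_free_frames_match_planted_templates(self, tiny_design, montage16):
        design = _noise_free(tiny_design)
        templates = synth.make_template_maps(
            design.n_maps, montage16, design.min_separation, seed=design.seed
        )
        epochs, _ = synth.simulate_epochs(design, montage16)
        ep = epochs[0]  # children, first subject, first condition
        label_index = {lab: i for i, lab in enumerate(design.state_labels)}
        for lab, on, off, amp in synth.state_windows(design, 0, 0):
            mid_ms = (on + off) / 2  # hann and plateau envelopes are both nonzero here
            tf = int(round(mid_ms * design.sampling_rate / 1000)) + design.pre_lock_tf
            if tf >= ep.n_times:
                continue
            r = spatial_correlation(ep.data[0, :, tf], templates[label_index[lab]])
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_scale_doubles_gfp(self, tiny_design, montage16):
        base = _asdict(_noise_free(tiny_design))
        base["group_amplitude_scale"] = (2.0, 1.0)
        base["group_latency_shift_ms"] = (0.0, 0.0)
        design = synth.SyntheticDesign(**base)
        epochs, _ = synth.simulate_epochs(design, montage16)
        by_group = {}
        for e in epochs:
            by_group.setdefault(e.group, []).append(e.data.mean(axis=0))
        g_children = gfp_series(Erp(np.mean(by_group["children"], axis=0), 512.0, 50))
        g_adults = gfp_series(Erp(np.mean(by_group["adults"], axis=0), 512.0, 50))
        tf = int(round(95 * 512 / 1000)) + 50  # centre of the first planted state
        assert g_children[tf] / g_adults[tf] == pytest.approx(2.0, abs=1e-6)

    def test_planted_latency_shift_recovered_from_gfp_peaks(self, montage16):
        shift_ms = 40.0
        base = _asdict(synth.SyntheticDesign(
            n_groups=2, n_subjects_per_group=10, n_trials=6, n_electrodes=16,
            group_names=("g1", "g2"), group_latency_shift_ms=(shift_ms, 0.0),
            group_amplitude_scale=(1.0, 1.0), rt_mean_ms=(900.0, 900.0),
            accuracy_logit_group=(0.0, 0.0), noise_sd_uv=0.2, seed=5,
        ))
        design = synth.SyntheticDesign(**base)
        epochs, _ = synth.simulate_epochs(design, montage16)
        peaks = {}
        for gname in design.group_names:
            data = np.mean(
                [e.data.mean(axis=0) for e in epochs if e.group == gname], axis=0
            )
            g = gfp_series(Erp(data, design.sampling_rate, design.pre_lock_tf))
            # first planted state peaks inside 40-230 ms
            lo = int(round(40 * 512 / 1000)) + 50
            hi = int(round(230 * 512 / 1000)) + 50
            peaks[gname] = lo + int(np.argmax(g[lo:hi]))
        dt_ms = (peaks["g1"] - peaks["g2"]) * 1000 / design.sampling_rate
        assert dt_ms == pytest.approx(shift_ms, abs=1000 / design.sampling_rate)

    def test_bit_exact_reproducibility(self, tiny_design, montage16):
        a, beh_a = synth.simulate_epochs(tiny_design, montage16)
        b, beh_b = synth.simulate_epochs(tiny_design, montage16)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))
        assert beh_a.equals(beh_b)
        other = synth.SyntheticDesign(**{**_asdict(tiny_design), "seed": 99})
        c, _ = synth.simulate_epochs(other, montage16)
        assert not np.array_equal(a[0].data, c[0].data)

    def test_epochs_are_average_referenced(self, tiny_design, montage16):
        epochs, _ = synth.simulate_epochs(tiny_design, montage16)
        dev = max(abs(e.data.mean(axis=1)).max() for e in epochs)
        assert dev < 1e-10

    def test_rt_moments_converge(self, montage16):
        design = synth.SyntheticDesign(
            n_groups=1, n_subjects_per_group=1, n_trials=10_000, n_electrodes=16,
            group_names=("g",), group_latency_shift_ms=(0.0,),
            group_amplitude_scale=(1.0,), rt_mean_ms=(900.0,),
            accuracy_logit_group=(0.0,), seed=2,
        )
        rng = synth._subject_rng(design, 0, 0, 0)
        rts, _ = synth._draw_behavior(design, rng, 0, 0)
        m, sd = synth.rt_moments(design, 0)
        se_mean = sd / np.sqrt(len(rts))
        assert abs(rts.mean() - m) < 3 * se_mean
        assert abs(rts.std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * len(rts))
        assert rts.min() >= design.rt_min_ms and rts.max() <= design.rt_max_ms


class TestResponseLocked:
    def test_window_arithmetic(self):
        # RT 800 ms at 512 Hz: window [110, 360) relative to picture onset
        from erpstates.alignment import ms_to_tf

        rt_tf = ms_to_tf(800.0, 512.0)
        assert rt_tf == 410
        assert (rt_tf - 50 - 250, rt_tf - 50) == (110, 360)

    def test_alignment_consistency_with_stimulus_epochs(self, tiny_design, montage16):
        design = _noise_free(tiny_design)
        stim, _ = synth.simulate_epochs(design, montage16)
        resp, dropped = synth.simulate_response_locked(design, montage16, stim)
        ep_s, ep_r = stim[0], resp[0]
        from erpstates.alignment import ms_to_tf

        for i in range(min(3, ep_r.n_trials)):
            trial = int(ep_r.trial_meta["trial"].iloc[i])
            rt_tf = ms_to_tf(float(ep_r.trial_meta["rt_ms"].iloc[i]), 512.0)
            start = rt_tf - 300  # window start relative to onset
            # overlap with the stimulus epoch frames [start+50, 300)
            n_overlap = 300 - (start + design.pre_lock_tf)
            if n_overlap <= 0:
                continue
            np.testing.assert_allclose(
                ep_r.data[i, :, :n_overlap],
                ep_s.data[trial, :, start + design.pre_lock_tf :],
                atol=1e-12,
            )

    def test_response_aligned_state_undistorted_only_in_response_lock(
        self, montage16
    ):
        # a response-anchored state smears in the stimulus-locked average but
        # aligns perfectly in the response-locked average
        design = synth.SyntheticDesign(
            n_groups=1, n_subjects_per_group=1, n_trials=30, n_electrodes=16,
            group_names=("g",), group_latency_shift_ms=(0.0,),
            group_amplitude_scale=(1.0,), rt_mean_ms=(900.0,), rt_sd_ms=250.0,
            accuracy_logit_group=(0.0,), noise_sd_uv=0.0, seed=3,
            state_sequence=(synth.StateSpec("A", -260.0, -150.0, 2.0, anchor="response"),),
        )
        template = synth.make_template_maps(1, montage16, seed=design.seed)[0]
        stim, _ = synth.simulate_epochs(design, montage16)
        resp, _ = synth.simulate_response_locked(design, montage16, stim)
        r_avg = resp[0].data.mean(axis=0)
        # state occupies frames ending ~150ms before vocal onset: pick its centre
        centre = resp[0].n_times - int(round((205 - 50 * 1000 / 512) * 512 / 1000))
        r_resp = spatial_correlation(r_avg[:, centre], template)
        assert r_resp == pytest.approx(1.0, abs=1e-9)
        s_avg = stim[0].data.mean(axis=0)
        g_stim = np.sqrt(np.mean(
            (s_avg - s_avg.mean(axis=0)) ** 2, axis=0))
        g_resp = np.sqrt(np.mean(
            (r_avg - r_avg.mean(axis=0)) ** 2, axis=0))
        # RT jitter smears the state in the stimulus-locked average
        assert g_stim.max() < 0.9 * g_resp.max()

    def test_invalid_design_rejected(self, tiny_design):
        with pytest.raises(ValueError, match="non-overlapping"):
            synth.SyntheticDesign(
                **{**_asdict(tiny_design), "state_sequence": (
                    synth.StateSpec("A", 100.0, 200.0, 1.0),
                    synth.StateSpec("B", 150.0, 250.0, 1.0),
                )}
            )
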