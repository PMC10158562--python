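import numpy as np
import pytest

from erpstates.containers import EpochSet, Erp
from erpstates.montage import make_hemisphere_montage
from erpstates.synth import SyntheticDesign, make_template_maps


@pytest.fixture(scope="session")
def montage16():
    return make_hemisphere_montage(16)


@pytest.fixture(scope="session")
def montage32():
    return make_hemisphere_montage(32)


@pytest.fixture(scope="session")
def templates4(montage16):
    return make_template_maps(4, montage16, min_separation=0.5, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_design():
    """2 groups x 3 subjects, 16 electrodes: cheap but structurally complete."""
    return SyntheticDesign(
        n_groups=2,
        n_subjects_per_group=3,
        n_trials=12,
        n_electrodes=16,
        group_names=("children", "adults"),
        group_latency_shift_ms=(40.0, 0.0),
        group_amplitude_scale=(1.3, 1.0),
        rt_mean_ms=(950.0, 820.0),
        accuracy_logit_group=(-0.5, 0.0),
        seed=7,
    )


def make_erp(data, fs=512.0, pre=0, lock="stimulus", **kw):
    return Erp(np.asarray(data, float), fs, pre, lock, **kw)


def make_epochs(data, fs=512.0, pre=50, lock="stimulus", **kw):
    return EpochSet(
        subject=kw.pop("subject", "s01"),
        group=kw.pop("group", "g1"),
        condition=kw.pop("condition", "c1"),
        lock=lock,
        data=np.asarray(data, float),
        sampling_rate=fs,
        pre_lock_tf=pre,
        trial_meta=kw.pop("trial_meta", None),
    )
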