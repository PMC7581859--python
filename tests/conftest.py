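"""Shared fixtures: small synthetic sessions, reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from bgamap import make_study_session
from bgamap.envelope import EpochSet, FS_ENV, EPOCH_K_MIN, EPOCH_K_MAX
from bgamap.preprocess import TrialMask


@pytest.fixture(scope="session")
def small_session():
    """Planted session: 3 scene-, 3 object-selective, 4 null channels, 30 trials/cat."""
    return make_study_session(
        seed=7, n_scene=3, n_object=3, n_null=4, n_unique=15,
        gain=0.4, onset=0.2, duration=0.3, spike_rate=0.02,
    )


@pytest.fixture(scope="session")
def small_run(small_session):
    from bgamap import PipelineConfig, run_pipeline

    return run_pipeline(small_session, PipelineConfig(seed=7))


def make_epochs(data: np.ndarray, labels, usable: np.ndarray | None = None) -> EpochSet:
    """EpochSet straight from an array (channels x trials x 64), for unit tests."""
    n_ch, n_tr, n_s = data.shape
    assert n_s == EPOCH_K_MAX - EPOCH_K_MIN + 1
    if usable is None:
        usable = np.ones((n_ch, n_tr), bool)
    mask = TrialMask(usable=usable, reason=np.full((n_ch, n_tr), "", object))
    return EpochSet(
        data=np.asarray(data, float),
        times=np.arange(EPOCH_K_MIN, EPOCH_K_MAX + 1) / FS_ENV,
        labels=np.asarray(labels, object),
        mask=mask,
        names=[f"c{i}" for i in range(n_ch)],
    )
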