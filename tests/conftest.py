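"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from fnirsdrive import features as F
from fnirsdrive import preprocess as P
from fnirsdrive import synth as S

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", module="sklearn")


def episode_windows(episodes, stride_s: float):
    """Preprocess episodes and collect slices with per-episode bookkeeping."""
    slices, owners = [], []
    for k, ep in enumerate(episodes):
        ss = P.process_episode(ep, stride_s=stride_s,
                               emit_from_s=S.BASELINE_S + P.SLICE_S)
        slices.extend(ss)
        owners.extend([k] * len(ss))
    return slices, np.array(owners)


@pytest.fixture(scope="session")
def zero_noise_data():
    """Six noiseless episodes: slices, raw features, labels, episodes."""
    episodes = S.generate_dataset(6, seed=7, noise=S.NoiseProfile.silent())
    slices, owners = episode_windows(episodes, stride_s=2.0)
    X, y = F.extract_dataset(slices)
    return {"episodes": episodes, "slices": slices, "owners": owners,
            "X": X, "y": y}


@pytest.fixture(scope="session")
def default_noise_data():
    """Ten episodes at the default physiological noise level."""
    episodes = S.generate_dataset(10, seed=11)
    slices, owners = episode_windows(episodes, stride_s=1.5)
    X, y = F.extract_dataset(slices)
    return {"episodes": episodes, "slices": slices, "owners": owners,
            "X": X, "y": y}
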