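from __future__ import annotations

import numpy as np
import pytest

from xenovasc import AnalysisConfig, VolumetricStack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_config():
    return AnalysisConfig()


def make_stack(channels: dict[str, np.ndarray], voxel_size=(5.0, 0.6, 0.6)) -> VolumetricStack:
    """Build a stack from role -> 3D array (shared shape)."""
    roles = {}
    arrays = []
    for i, (role, arr) in enumerate(channels.items()):
        roles[role] = i
        arrays.append(np.asarray(arr, dtype=float))
    return VolumetricStack(np.stack(arrays), roles, voxel_size)


@pytest.fixture
def make_stack_fixture():
    return make_stack
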