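import numpy as np
import pytest

from behavstate import (
    BinnedDataset,
    Pedigree,
    StateParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def tiny_dataset():
    """Six observations of two animals over two behaviors (3 and 2 levels)."""
    return BinnedDataset(
        levels=np.array(
            [[1, 1], [2, 2], [3, 1], [1, 2], [2, 1], [3, 2]], dtype=np.int64
        ),
        animal_index=np.array([0, 0, 0, 1, 1, 1]),
        animal_ids=["a", "b"],
        behavior_names=["groom", "feed"],
        n_levels=np.array([3, 2]),
    )


@pytest.fixture
def uniform_states():
    """Two identical states, uniform over each behavior's levels."""
    theta = np.zeros((2, 2, 3))
    theta[:, 0, :] = 1 / 3
    theta[:, 1, :2] = 1 / 2
    return StateParams(theta=theta, n_levels=np.array([3, 2]))


@pytest.fixture
def sib_pedigree():
    """Four founders, two full-sib pairs (8 individuals)."""
    return Pedigree(
        (
            ("f1", "", ""),
            ("f2", "", ""),
            ("f3", "", ""),
            ("f4", "", ""),
            ("c1", "f1", "f2"),
            ("c2", "f1", "f2"),
            ("c3", "f3", "f4"),
            ("c4", "f3", "f4"),
        )
    )
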