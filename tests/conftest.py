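import numpy as np
import pytest

from bbtd.integration import SubtreeDataset


def make_chain_dataset(states: np.ndarray, gene_names=None) -> SubtreeDataset:
    """Dataset over a single cell: points form one unbranched chain."""
    states = np.asarray(states, dtype=np.int8)
    n, t = states.shape
    return SubtreeDataset(
        states=states,
        missing=np.zeros((n, t), dtype=bool),
        gene_names=gene_names or [f"g{i}" for i in range(n)],
        cell_of_point=np.array(["cell"] * t),
        prev=np.arange(-1, t - 1),
    )


def make_forked_dataset(states: np.ndarray, split: int) -> SubtreeDataset:
    """Dataset over a parent cell and two daughters sharing its history.

    The parent owns points 0..split-1; the two daughters each own the
    same number of subsequent points and both link back to the parent's
    terminal point.
    """
    states = np.asarray(states, dtype=np.int8)
    n, t = states.shape
    rest = t - split
    assert rest % 2 == 0 and rest > 0
    half = rest // 2
    prev = np.empty(t, dtype=np.int64)
    prev[:split] = np.arange(-1, split - 1)
    prev[split] = split - 1
    prev[split + 1 : split + half] = np.arange(split, split + half - 1)
    prev[split + half] = split - 1
    prev[split + half + 1 :] = np.arange(split + half, t - 1)
    cells = np.array(
        ["P"] * split + ["Pa"] * half + ["Pp"] * half
    )
    return SubtreeDataset(
        states=states,
        missing=np.zeros((n, t), dtype=bool),
        gene_names=[f"g{i}" for i in range(n)],
        cell_of_point=cells,
        prev=prev,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture
def small_random_dataset(rng):
    """A 3-gene chain of 20 random states."""
    return make_chain_dataset(rng.integers(0, 2, size=(3, 20)))
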