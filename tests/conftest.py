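from __future__ import annotations

import numpy as np
import pytest

from calixtda.chemio import MoleculePointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_cloud_factory():
    """Factory for random carbon clouds of a given size and scale."""

    def make(n: int, seed: int, scale: float = 2.0) -> MoleculePointCloud:
        r = np.random.default_rng(seed)
        return MoleculePointCloud(
            id=f"random-{n}-{seed}",
            elements=("C",) * n,
            coords=r.normal(size=(n, 3)) * scale,
        )

    return make


@pytest.fixture
def thirty_atom_cloud(rng):
    symbols = tuple(rng.choice(["C", "H", "O", "N", "S", "F"], size=30))
    return MoleculePointCloud(
        id="fixture-30", elements=symbols, coords=rng.normal(size=(30, 3)) * 3
    )
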