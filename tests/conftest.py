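"""Shared fixtures: toy atlases and a small, fast cohort configuration."""

from __future__ import annotations

import numpy as np
import pytest

from sfc_aging.cohort import CohortConfig
from sfc_aging.io import LabelEntry, LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def row_atlas():
    """1D row [ventricle, caudate, caudate, caudate] embedded in a 3D grid."""
    labels = np.zeros((4, 1, 1), dtype=np.int32)
    labels[0] = 1
    labels[1:] = 2
    return LabelVolume(
        labels,
        {1: LabelEntry("ventricle", "ventricle"), 2: LabelEntry("caudate_left", "caudate_left")},
    )


@pytest.fixture
def corner_atlas():
    """Ventricle at a corner; caudate voxels at face-, corner- and far positions."""
    labels = np.zeros((3, 2, 2), dtype=np.int32)
    labels[0, 0, 0] = 1  # ventricle
    labels[1, 0, 0] = 2  # face-adjacent caudate
    labels[1, 1, 1] = 2  # corner-adjacent caudate (26-connectivity only)
    labels[2, 1, 1] = 2  # never adjacent
    return LabelVolume(
        labels,
        {1: LabelEntry("ventricle", "ventricle"), 2: LabelEntry("caudate_left", "caudate_left")},
    )


@pytest.fixture
def small_config():
    """A cohort small enough for sub-second generation."""
    return CohortConfig(
        n_per_group=(6, 4, 4), grid_dims=(8, 8, 8), n_parcels=10, n_timepoints=80, seed=11
    )


def exhaustive_walk_counts(adjacency: np.ndarray, seed_nodes: np.ndarray, max_step: int) -> dict[int, np.ndarray]:
    """Independent oracle: count length-k walks from seed nodes by enumeration."""
    n = adjacency.shape[0]
    neighbours = [np.flatnonzero(adjacency[i]).tolist() for i in range(n)]
    counts = {k: np.zeros(n) for k in range(1, max_step + 1)}

    def walk(node: int, depth: int) -> None:
        for nb in neighbours[node]:
            counts[depth][nb] += 1
            if depth < max_step:
                walk(nb, depth + 1)

    for s in seed_nodes:
        walk(int(s), 1)
    return counts
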