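"""Shared fixtures.

Heavy objects (dictionary, subspace, simulated acquisitions) are
session-scoped so the expensive acceptance-grade pipeline runs once and is
shared by all tests that inspect it.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import stackmrf as sm


@pytest.fixture(scope="session")
def small_seq() -> sm.SequenceParams:
    """Short 32-frame train for cheap unit tests."""
    return sm.SequenceParams.default(32)


@pytest.fixture(scope="session")
def small_grid() -> sm.DictionaryGrid:
    return sm.DictionaryGrid(
        t1_values_ms=np.geomspace(50, 3000, 20),
        t2_values_ms=np.geomspace(10, 1500, 20),
    )


@pytest.fixture(scope="session")
def small_dictionary(small_seq, small_grid) -> sm.Dictionary:
    return sm.build_dictionary(small_seq, small_grid)


@pytest.fixture(scope="session")
def small_subspace(small_dictionary) -> sm.TemporalSubspace:
    return sm.compute_subspace(small_dictionary, 5)


@pytest.fixture(scope="session")
def default_seq() -> sm.SequenceParams:
    """Desk-scale reference protocol (256 frames)."""
    return sm.SequenceParams.default(256)


@pytest.fixture(scope="session")
def default_dictionary(default_seq) -> sm.Dictionary:
    return sm.build_dictionary(default_seq, sm.DictionaryGrid.default())


@pytest.fixture(scope="session")
def default_subspace(default_dictionary) -> sm.TemporalSubspace:
    return sm.compute_subspace(default_dictionary, 5)


def make_tiny_system(
    n=16, nz=4, T=8, R=2, n_coils=2, K=2, seed=0, readout=None
):
    """Small random forward-model problem for operator tests."""
    rng = np.random.default_rng(seed)
    sampling = sm.make_kt_sampling(
        T, nz, R, readout_samples=readout if readout else 2 * n
    )
    basis = rng.standard_normal((T, K)) + 1j * rng.standard_normal((T, K))
    basis, _ = np.linalg.qr(basis)
    coil_maps = (
        rng.standard_normal((n_coils, R, n, n))
        + 1j * rng.standard_normal((n_coils, R, n, n))
    ) / np.sqrt(n_coils)
    from stackmrf.operators import FusedSubspaceGridding, SliceGroupSystem

    fused = FusedSubspaceGridding(basis, sampling, n)
    system = SliceGroupSystem(fused, coil_maps, sampling)
    return system, basis, coil_maps, sampling, rng
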