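"""Fingerprint dictionary over a (T1, T2) grid and its temporal subspace.

The dictionary D stacks one simulated fingerprint per physically admissible
(T1, T2) grid pair, L2-normalized per row for dot-product matching.  Its
leading right singular vectors span the temporal subspace: every plausible
voxel signal is, to good approximation, a combination of the first K basis
vectors, so the reconstruction can solve for K coefficient images instead
of T contrast images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import scipy.linalg

from .epg import simulate_fingerprints
from .sequence import SequenceParams

__all__ = [
    "DictionaryGrid",
    "Dictionary",
    "TemporalSubspace",
    "build_dictionary",
    "compute_subspace",
]


@dataclass
class DictionaryGrid:
    """Cartesian product of T1/T2 values, keeping only pairs with T2 <= T1."""

    t1_values_ms: np.ndarray
    t2_values_ms: np.ndarray

    def __post_init__(self) -> None:
        self.t1_values_ms = np.asarray(self.t1_values_ms, dtype=float)
        self.t2_values_ms = np.asarray(self.t2_values_ms, dtype=float)
        for vals, name in ((self.t1_values_ms, "t1"), (self.t2_values_ms, "t2")):
            if vals.size == 0 or np.any(vals <= 0):
                raise ValueError(f"{name} values must be non-empty and positive")
            if np.any(np.diff(vals) <= 0):
                raise ValueError(f"{name} values must be strictly ascending")
        t1g, t2g = np.meshgrid(self.t1_values_ms, self.t2_values_ms, indexing="ij")
        keep = t2g <= t1g
        self.entries = np.stack([t1g[keep], t2g[keep]], axis=1)
        if self.entries.shape[0] == 0:
            raise ValueError("grid has no physically admissible (t1, t2) pairs")

    @property
    def n_entries(self) -> int:
        return int(self.entries.shape[0])

    @classmethod
    def default(cls) -> "DictionaryGrid":
        """Log-spaced 60x60 grid: T1 10..3000 ms, T2 5..1500 ms.

        Brackets both the NiCl2 contrast-sphere range of the NIST/ISMRM
        system phantom and in vivo tissue values.
        """
        return cls(
            t1_values_ms=np.geomspace(10.0, 3000.0, 60),
            t2_values_ms=np.geomspace(5.0, 1500.0, 60),
        )

    def snap(self, t1_ms: float, t2_ms: float) -> tuple[float, float]:
        """Nearest admissible grid pair to the requested (t1, t2)."""
        d = np.abs(np.log(self.entries[:, 0]) - np.log(t1_ms)) + np.abs(
            np.log(self.entries[:, 1]) - np.log(t2_ms)
        )
        i = int(np.argmin(d))
        return float(self.entries[i, 0]), float(self.entries[i, 1])


@dataclass
class Dictionary:
    """Fingerprint matrix (n_entries x T) with its grid.

    ``signals`` rows are unit L2 norm when ``normalized``; ``scales`` keeps
    the pre-normalization row norms so matching can recover the proton
    density scale.
    """

    signals: np.ndarray
    grid: DictionaryGrid
    normalized: bool
    scales: np.ndarray | None = None

    @property
    def n_entries(self) -> int:
        return int(self.signals.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.signals.shape[1])

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=self.signals)
            f.create_dataset("t1_ms", data=self.grid.entries[:, 0])
            f.create_dataset("t2_ms", data=self.grid.entries[:, 1])
            f.create_dataset("t1_axis_ms", data=self.grid.t1_values_ms)
            f.create_dataset("t2_axis_ms", data=self.grid.t2_values_ms)
            if self.scales is not None:
                f.create_dataset("scales", data=self.scales)
            f.attrs["normalized"] = self.normalized

    @classmethod
    def load(cls, path: str | Path) -> "Dictionary":
        with h5py.File(path, "r") as f:
            grid = DictionaryGrid(f["t1_axis_ms"][:], f["t2_axis_ms"][:])
            sig = f["signals"][:]
            scales = f["scales"][:] if "scales" in f else None
            normalized = bool(f.attrs["normalized"])
        d = cls(signals=sig, grid=grid, normalized=normalized, scales=scales)
        # the admissibility filter must reproduce the stored entry order
        if d.n_entries != sig.shape[0]:
            raise ValueError("stored signals inconsistent with stored grid axes")
        return d


@dataclass
class TemporalSubspace:
    """Orthonormal temporal basis (T x K) from the dictionary SVD."""

    basis: np.ndarray
    rank: int

    def __post_init__(self) -> None:
        if self.basis.shape[1] != self.rank:
            raise ValueError("basis column count must equal rank")

    @property
    def n_frames(self) -> int:
        return int(self.basis.shape[0])

    def compress(self, time_signals: np.ndarray) -> np.ndarray:
        """Project time-domain signals (..., T) to coefficients (..., K)."""
        return time_signals @ np.conj(self.basis)

    def expand(self, coeffs: np.ndarray) -> np.ndarray:
        """Expand coefficients (..., K) back to time-domain signals (..., T)."""
        return coeffs @ self.basis.T


def build_dictionary(seq: SequenceParams, grid: DictionaryGrid) -> Dictionary:
    """Simulate and row-normalize one fingerprint per grid entry.

    B1+ variation is deliberately not a dictionary dimension.
    """
    if grid.n_entries == 0:
        raise ValueError("empty dictionary grid")
    sig = simulate_fingerprints(seq, grid.entries[:, 0], grid.entries[:, 1])
    norms = np.linalg.norm(sig, axis=1)
    if np.any(norms == 0):
        raise ValueError("grid produced an all-zero fingerprint; check the sequence")
    return Dictionary(
        signals=sig / norms[:, None], grid=grid, normalized=True, scales=norms
    )


def compute_subspace(dictionary: Dictionary, rank: int) -> TemporalSubspace:
    """Temporal subspace: leading right singular vectors of the dictionary."""
    n, T = dictionary.signals.shape
    if not (1 <= rank <= min(n, T)):
        raise ValueError(f"rank must be in [1, {min(n, T)}], got {rank}")
    _, _, vh = scipy.linalg.svd(dictionary.signals, full_matrices=False)
    # rows of Vh span the row space: time signals x satisfy x = basis @ a
    # with a = basis^H x, so the basis columns are Vh rows transposed
    # (no conjugation — conjugating changes the span for complex signals)
    basis = vh[:rank].T.copy()  # (T, rank), orthonormal columns
    return TemporalSubspace(basis=basis, rank=rank)
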