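"""Stack-of-stars k-t sampling: tiny-golden-angle spokes and CAIPIRINHA kz.

Each MRF frame acquires a single radial spoke whose azimuthal angle advances
by a constant tiny-golden-angle increment.  Through-plane, the kz partition
encoding is undersampled by an integer factor R; the set of partitions
sampled at frame t is shifted by (t mod R), i.e. the frame index cycles
through the R interleaves of the kz grid.  After a per-frame inverse DFT
along the sampled kz subgrid, each of the R slices aliased into a group
carries a frame-dependent phase given by the Fourier shift theorem — the
CAIPIRINHA phase modulation the reconstruction exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "KTSampling",
    "CaipiPhase",
    "make_kt_sampling",
    "caipi_phase",
    "spoke_coordinates",
    "TINY_GOLDEN_ANGLE_7",
]

# 7th tiny golden angle: pi / (golden ratio + 6) ~= 23.628 degrees
TINY_GOLDEN_ANGLE_7 = np.pi / ((1.0 + np.sqrt(5.0)) / 2.0 + 6.0)


@dataclass
class KTSampling:
    """k-t sampling pattern of a through-plane accelerated stack-of-stars scan.

    ``kz_indices[t]`` lists the Nz/R partitions sampled at frame t (all at
    the same spoke angle); for R=1 every frame samples all Nz partitions.
    """

    n_frames: int
    spoke_angle_rad: np.ndarray
    kz_indices: np.ndarray  # (T, Nz // R), ascending per frame
    reduction_factor: int
    n_partitions: int
    readout_samples: int
    kz_cycle_origin: int = 0
    angle_increment_rad: float = TINY_GOLDEN_ANGLE_7

    @property
    def n_sampled_partitions(self) -> int:
        return self.n_partitions // self.reduction_factor

    def kz_offset(self, frame: int) -> int:
        """Interleave offset o(t) in [0, R) of the frame's kz comb."""
        return int(self.kz_indices[frame, 0]) % self.reduction_factor

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("spoke_angle_rad", data=self.spoke_angle_rad)
            f.create_dataset("kz_indices", data=self.kz_indices)
            f.attrs.update(
                R=self.reduction_factor,
                Nz=self.n_partitions,
                T=self.n_frames,
                readout_samples=self.readout_samples,
                kz_cycle_origin=self.kz_cycle_origin,
                angle_increment_rad=self.angle_increment_rad,
            )

    @classmethod
    def load(cls, path: str | Path) -> "KTSampling":
        with h5py.File(path, "r") as f:
            return cls(
                n_frames=int(f.attrs["T"]),
                spoke_angle_rad=f["spoke_angle_rad"][:],
                kz_indices=f["kz_indices"][:],
                reduction_factor=int(f.attrs["R"]),
                n_partitions=int(f.attrs["Nz"]),
                readout_samples=int(f.attrs["readout_samples"]),
                kz_cycle_origin=int(f.attrs["kz_cycle_origin"]),
                angle_increment_rad=float(f.attrs["angle_increment_rad"]),
            )


@dataclass
class CaipiPhase:
    """Per-frame unit-modulus phase on each aliased slice replicate (T x R)."""

    phase: np.ndarray


def make_kt_sampling(
    n_frames: int,
    n_partitions: int,
    reduction_factor: int,
    angle_increment_rad: float = TINY_GOLDEN_ANGLE_7,
    seed_angle_rad: float = 0.0,
    readout_samples: int | None = None,
    kz_cycle_origin: int = 0,
) -> KTSampling:
    """Build the k-t pattern: one spoke angle per frame, R-cycled kz comb.

    Frame t samples partitions {(t + origin) mod R + m*R} at angle
    seed + t*increment.  R must divide Nz.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if reduction_factor < 1 or n_partitions % reduction_factor != 0:
        raise ValueError(
            f"reduction factor {reduction_factor} must divide Nz={n_partitions}"
        )
    t = np.arange(n_frames)
    angles = np.mod(seed_angle_rad + t * angle_increment_rad, 2 * np.pi)
    offsets = (t + kz_cycle_origin) % reduction_factor
    m = np.arange(n_partitions // reduction_factor)
    kz = offsets[:, None] + m[None, :] * reduction_factor
    return KTSampling(
        n_frames=n_frames,
        spoke_angle_rad=angles,
        kz_indices=kz,
        reduction_factor=reduction_factor,
        n_partitions=n_partitions,
        readout_samples=readout_samples if readout_samples is not None else 0,
        kz_cycle_origin=kz_cycle_origin,
        angle_increment_rad=angle_increment_rad,
    )


def caipi_phase(sampling: KTSampling) -> CaipiPhase:
    """Fourier-shift phases of the aliased replicates, shape (T, R).

    Replicate r of a slice group sits r * Nz/R partitions away along z; a
    kz-comb offset of o(t) partitions therefore modulates it by
    exp(-2i*pi*o(t)*r/R).  For R=2 the shifted replicate alternates +1/-1
    frame to frame; for R=1 the matrix is all ones.
    """
    R = sampling.reduction_factor
    offsets = np.array([sampling.kz_offset(t) for t in range(sampling.n_frames)])
    r = np.arange(R)
    return CaipiPhase(phase=np.exp(-2j * np.pi * offsets[:, None] * r[None, :] / R))


def spoke_coordinates(sampling: KTSampling, frame: int) -> np.ndarray:
    """In-plane k-space coordinates of one spoke, shape (readout_samples, 2).

    ``readout_samples`` points along a diameter at the frame's angle, with
    radii (j - n/2)/n in cycles/pixel for j = 0..n-1, i.e. covering
    [-0.5, 0.5) and containing the k-space origin at j = n/2 when n is
    even.  Column order is (kx, ky).
    """
    if not (0 <= frame < sampling.n_frames):
        raise ValueError(f"frame {frame} out of range [0, {sampling.n_frames})")
    n = sampling.readout_samples
    if n < 1:
        raise ValueError("sampling has no readout_samples set")
    radius = (np.arange(n) - n // 2) / n
    ang = sampling.spoke_angle_rad[frame]
    return np.stack([radius * np.cos(ang), radius * np.sin(ang)], axis=1)
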