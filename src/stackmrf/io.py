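"""HDF5 raw-data container and NIfTI export helpers.

Raw container layout::

    /kspace            complex (T, n_kz_per_frame, readout, n_coils)
    /sampling/spoke_angle_rad, /sampling/kz_indices
    /coils/maps        optional complex (n_coils, Nz, N, N)
    attrs: N, Nz, R, T, readout_samples, kz_cycle_origin,
           angle_increment_rad, noise_sd, field_strength_t, tr_ms
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .operators import CoilSensitivities, KSpaceData
from .sampling import KTSampling

__all__ = ["save_raw", "load_raw", "save_volume_nifti", "save_coils_nifti"]


def save_raw(
    path: str | Path,
    data: KSpaceData,
    im_size: int,
    coils: CoilSensitivities | None = None,
    field_strength_t: float = 0.35,
    tr_ms: float = 12.0,
) -> None:
    s = data.sampling
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=data.samples)
        g = f.create_group("sampling")
        g.create_dataset("spoke_angle_rad", data=s.spoke_angle_rad)
        g.create_dataset("kz_indices", data=s.kz_indices)
        if coils is not None:
            f.create_group("coils").create_dataset("maps", data=coils.maps)
        f.attrs.update(
            N=im_size,
            Nz=s.n_partitions,
            R=s.reduction_factor,
            T=s.n_frames,
            readout_samples=s.readout_samples,
            kz_cycle_origin=s.kz_cycle_origin,
            angle_increment_rad=s.angle_increment_rad,
            noise_sd=data.noise_sd if data.noise_sd is not None else -1.0,
            field_strength_t=field_strength_t,
            tr_ms=tr_ms,
        )


def load_raw(path: str | Path) -> tuple[KSpaceData, CoilSensitivities | None, int]:
    """Returns (k-space data, coil maps or None, in-plane matrix size)."""
    with h5py.File(path, "r") as f:
        sampling = KTSampling(
            n_frames=int(f.attrs["T"]),
            spoke_angle_rad=f["sampling/spoke_angle_rad"][:],
            kz_indices=f["sampling/kz_indices"][:],
            reduction_factor=int(f.attrs["R"]),
            n_partitions=int(f.attrs["Nz"]),
            readout_samples=int(f.attrs["readout_samples"]),
            kz_cycle_origin=int(f.attrs["kz_cycle_origin"]),
            angle_increment_rad=float(f.attrs["angle_increment_rad"]),
        )
        noise_sd = float(f.attrs["noise_sd"])
        data = KSpaceData(
            samples=f["kspace"][:],
            sampling=sampling,
            noise_sd=None if noise_sd < 0 else noise_sd,
        )
        coils = (
            CoilSensitivities(maps=f["coils/maps"][:]) if "coils" in f else None
        )
        n = int(f.attrs["N"])
    return data, coils, n


def save_volume_nifti(
    path: str | Path, volume: np.ndarray, voxel_size_mm: tuple[float, float, float]
) -> None:
    """Write an (Nz, ..., N, N) real volume as (N, N, [ch,] Nz) NIfTI."""
    vol = np.moveaxis(np.asarray(volume), 0, -1)
    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), str(path))


def save_coils_nifti(
    out_dir: str | Path,
    coils: CoilSensitivities,
    voxel_size_mm: tuple[float, float, float],
) -> None:
    """Export coil maps as magnitude/phase NIfTI pairs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume_nifti(out / "coils_mag.nii.gz", np.abs(coils.maps).transpose(1, 0, 2, 3), voxel_size_mm)
    save_volume_nifti(out / "coils_phase.nii.gz", np.angle(coils.maps).transpose(1, 0, 2, 3), voxel_size_mm)
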