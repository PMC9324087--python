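"""Post-processing: non-local-means denoising, dictionary matching, cropping.

After the inverse problem is solved, the K subspace coefficient images are
(for accelerated data) denoised slice-wise with non-local means and then
matched voxel-by-voxel against the fingerprint dictionary by maximum
normalized dot product, yielding T1, T2, proton-density M0 and a match
quality score per voxel.  Matching happens in the K-dimensional compressed
domain against the projected dictionary, which for subspace-reconstructed
data is equivalent to time-domain matching up to the (negligible)
projection residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.ndimage

from .dictionary import Dictionary, TemporalSubspace

__all__ = [
    "ParameterMaps",
    "nlm_denoise",
    "estimate_noise_sd",
    "match_dictionary",
    "crop_oversampled_slices",
]


@dataclass
class ParameterMaps:
    """Quantitative maps: T1/T2 (ms), M0, match score, validity mask.

    All volumes share the shape (Nz, N, N).  Voxels whose best match score
    falls below the validity threshold are flagged invalid and carry zero
    relaxation times.
    """

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    m0: np.ndarray
    match_score: np.ndarray
    valid: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.64, 1.64, 5.0)

    def save(self, out_dir: str | Path) -> None:
        """Write t1/t2/m0 magnitude/score volumes as NIfTI with voxel size."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        # volumes are (Nz, N, N); store as (N, N, Nz) spatial order
        zoom = (self.voxel_size_mm[0], self.voxel_size_mm[1], self.voxel_size_mm[2])
        affine = np.diag([*zoom, 1.0])
        for name, vol in (
            ("t1", self.t1_ms),
            ("t2", self.t2_ms),
            ("m0_mag", np.abs(self.m0)),
            ("score", self.match_score),
        ):
            img = nib.Nifti1Image(
                np.ascontiguousarray(np.moveaxis(vol, 0, -1)).astype(np.float64),
                affine,
            )
            nib.save(img, out / f"{name}.nii.gz")


def estimate_noise_sd(image: np.ndarray) -> float:
    """Robust noise estimate from the high-frequency residual of an image.

    Median absolute deviation of the discrete Laplacian, scaled by the
    filter's noise gain (sqrt(sum of squared taps) = 6) and the normal MAD
    constant.  Real and imaginary parts are pooled for complex input.
    """
    lap = np.array([[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]])
    parts = [image.real, image.imag] if np.iscomplexobj(image) else [image]
    resid = np.concatenate(
        [scipy.ndimage.convolve(p, lap, mode="reflect").ravel() for p in parts]
    )
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))) / 6.0)


def nlm_denoise(
    image: np.ndarray,
    patch: int = 3,
    search: int = 32,
    strength: float | None = None,
) -> np.ndarray:
    """Non-local-means denoising of one 2-D (possibly complex) image.

    Each pixel becomes a weighted average over candidates in its search
    window; the weight of a candidate is exp(-d^2 / h^2) where d^2 is the
    mean squared patch difference (real and imaginary parts jointly, one
    weight set for both).  Weights are normalized to sum to one, so a
    constant image is a fixed point and as h -> infinity the output tends
    to the local search-window mean.

    Parameters
    ----------
    patch : odd int
        Side of the square comparison patch (default 3).
    search : int
        Side of the search window (default 32); offsets span
        [-search//2, search//2].
    strength : float, optional
        The filter bandwidth h.  Default: 1.5 times the noise level
        estimated from the image's high-frequency residual.
    """
    if patch % 2 != 1 or patch < 1:
        raise ValueError("patch size must be odd and positive")
    if search < patch:
        raise ValueError("search window must be at least the patch size")
    img = np.asarray(image)
    img = img.astype(complex if np.iscomplexobj(img) else float)
    if img.ndim != 2:
        raise ValueError("nlm_denoise operates on single 2-D images")
    if strength is None:
        strength = 1.5 * estimate_noise_sd(img)
    if strength <= 0:
        return img.copy()

    half = search // 2
    pad = half + patch // 2
    padded = np.pad(img, pad, mode="reflect")
    n0, n1 = img.shape
    num = np.zeros(img.shape, dtype=padded.dtype)
    den = np.zeros(img.shape, dtype=float)
    core = padded[pad - patch // 2 : pad + n0 + patch // 2,
                  pad - patch // 2 : pad + n1 + patch // 2]
    h2 = float(strength) ** 2
    for dx in range(-half, half + 1):
        for dy in range(-half, half + 1):
            shifted = padded[
                pad + dx - patch // 2 : pad + dx + n0 + patch // 2,
                pad + dy - patch // 2 : pad + dy + n1 + patch // 2,
            ]
            d2 = scipy.ndimage.uniform_filter(
                np.abs(core - shifted) ** 2, size=patch
            )[patch // 2 : patch // 2 + n0, patch // 2 : patch // 2 + n1]
            w = np.exp(-d2 / h2)
            num += w * shifted[patch // 2 : patch // 2 + n0,
                               patch // 2 : patch // 2 + n1]
            den += w
    return num / den


def match_dictionary(
    coefficients: np.ndarray,
    dictionary: Dictionary,
    subspace: TemporalSubspace | None = None,
    score_threshold: float = 0.1,
    voxel_size_mm: tuple[float, float, float] = (1.64, 1.64, 5.0),
    chunk: int = 4096,
) -> ParameterMaps:
    """Voxelwise maximum-dot-product dictionary matching.

    Parameters
    ----------
    coefficients : ndarray
        Either subspace coefficient volumes (Nz, K, N, N) — matched in the
        compressed domain against the projected dictionary (requires
        ``subspace``) — or time-domain signals (Nz, T, N, N) matched
        directly.
    dictionary : Dictionary
        Must be row-normalized.
    score_threshold : float
        Voxels with best |dot| / ||signal|| below this are flagged invalid.

    The matched entry's (T1, T2) label the voxel; M0 is the complex dot
    product divided by the entry's pre-normalization signal norm, which
    recovers the proton-density scale; the match score is phase-insensitive.
    """
    if not dictionary.normalized:
        raise ValueError("dictionary must be row-normalized for matching")
    vols = np.asarray(coefficients)
    if vols.ndim != 4:
        raise ValueError("expect (Nz, n_channels, N, N) input")
    nz, nch, n0, n1 = vols.shape
    if subspace is not None:
        if nch != subspace.rank:
            raise ValueError("channel count does not match the subspace rank")
        # projected dictionary rows Phi^H d, renormalized to unit length in
        # the compressed domain: matching is against unit-norm atoms in the
        # space the comparison actually happens in (otherwise entries with
        # larger in-subspace energy are systematically favored)
        dict_rows = dictionary.signals @ np.conj(subspace.basis)  # (n_entries, K)
        row_norms = np.linalg.norm(dict_rows, axis=1)
        if np.any(row_norms == 0):
            raise ValueError("a dictionary entry is orthogonal to the subspace")
        dict_rows = dict_rows / row_norms[:, None]
    else:
        if nch != dictionary.n_frames:
            raise ValueError("channel count matches neither subspace nor frames")
        dict_rows = dictionary.signals
        row_norms = np.ones(dictionary.n_entries)

    signals = vols.transpose(0, 2, 3, 1).reshape(-1, nch)  # (n_vox, nch)
    n_vox = signals.shape[0]
    best_idx = np.zeros(n_vox, dtype=np.int64)
    best_dot = np.zeros(n_vox, dtype=complex)
    for lo in range(0, n_vox, chunk):
        block = signals[lo : lo + chunk]
        dots = block @ np.conj(dict_rows).T  # (chunk, n_entries)
        idx = np.argmax(np.abs(dots), axis=1)
        best_idx[lo : lo + chunk] = idx
        best_dot[lo : lo + chunk] = dots[np.arange(block.shape[0]), idx]

    norms = np.linalg.norm(signals, axis=1)
    score = np.zeros(n_vox)
    nonzero = norms > 0
    score[nonzero] = np.abs(best_dot[nonzero]) / norms[nonzero]
    np.clip(score, 0.0, 1.0, out=score)
    valid = score >= score_threshold

    t1 = np.where(valid, dictionary.grid.entries[best_idx, 0], 0.0)
    t2 = np.where(valid, dictionary.grid.entries[best_idx, 1], 0.0)
    scales = (
        dictionary.scales[best_idx]
        if dictionary.scales is not None
        else np.ones(n_vox)
    )
    # signal = m0 * fingerprint, so the complex dot with the unit atom is
    # m0 times the fingerprint's norm inside the matching space
    m0 = np.where(valid, best_dot / (scales * row_norms[best_idx]), 0.0)

    shape = (nz, n0, n1)
    return ParameterMaps(
        t1_ms=t1.reshape(shape),
        t2_ms=t2.reshape(shape),
        m0=m0.reshape(shape),
        match_score=score.reshape(shape),
        valid=valid.reshape(shape),
        voxel_size_mm=voxel_size_mm,
    )


def crop_oversampled_slices(
    maps: ParameterMaps, oversampling_fraction: float
) -> ParameterMaps:
    """Remove the slice-oversampling margin symmetrically.

    With fraction f, the acquired Nz partitions cover (1 + f) times the
    prescribed slab, so the central Nz / (1 + f) slices are kept (40 -> 32
    for 25% oversampling).  The crop must come out integer and symmetric.
    """
    if not (0 <= oversampling_fraction < 1):
        raise ValueError("oversampling fraction must be in [0, 1)")
    if oversampling_fraction == 0:
        return maps
    nz = maps.t1_ms.shape[0]
    keep = nz / (1.0 + oversampling_fraction)
    if abs(keep - round(keep)) > 1e-9:
        raise ValueError(
            f"{nz} partitions with {oversampling_fraction:.0%} oversampling do "
            f"not crop to an integer slice count; choose Nz divisible by "
            f"(1 + fraction)"
        )
    keep = int(round(keep))
    lo = (nz - keep) // 2
    sl = slice(lo, lo + keep)
    return ParameterMaps(
        t1_ms=maps.t1_ms[sl],
        t2_ms=maps.t2_ms[sl],
        m0=maps.m0[sl],
        match_score=maps.match_score[sl],
        valid=maps.valid[sl],
        voxel_size_mm=maps.voxel_size_mm,
    )
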