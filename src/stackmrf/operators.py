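"""Linear operators of the subspace reconstruction forward model.

The accelerated acquisition is modeled, per aliased slice group, as

    y = S Theta F B C x

where ``x`` holds K subspace coefficient images for each of the R slices
aliased into the group, ``C`` multiplies by coil sensitivities, ``B``
expands K coefficients to T contrast frames with the temporal basis, ``F``
evaluates each frame on its radial spoke (NUFFT), ``Theta`` applies the
frame-by-frame CAIPIRINHA phases, and ``S`` sums the aliased replicates
(scaled by 1/sqrt(R) to keep the hybrid kz decode unitary).  The basis
expansion and the gridding interpolation commute into a single sparse
structure so each operator application costs K (not T) oversampled FFTs
plus one sparse matrix product over all T spokes.

``hybrid_decode`` turns raw (frame, kz, readout, coil) data into the
per-slice-group hybrid data this model addresses, by a unitary inverse DFT
along the sampled kz comb of each frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.sparse

from .dictionary import TemporalSubspace
from .nufft import NufftPlan
from .sampling import KTSampling, caipi_phase, spoke_coordinates

__all__ = [
    "CoilSensitivities",
    "KSpaceData",
    "hybrid_decode",
    "combine_gridding_with_subspace",
    "FusedSubspaceGridding",
    "SliceGroupSystem",
    "estimate_sensitivities",
]


@dataclass
class CoilSensitivities:
    """Complex coil maps, shape (n_coils, Nz, N, N), one per true slice."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        if self.maps.ndim != 4:
            raise ValueError("coil maps must be (n_coils, Nz, N, N)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("coil maps contain non-finite values")

    @property
    def n_coils(self) -> int:
        return int(self.maps.shape[0])


@dataclass
class KSpaceData:
    """Raw k-t samples, shape (T, n_kz_per_frame, readout, n_coils)."""

    samples: np.ndarray
    sampling: KTSampling
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        T, n_kz = self.samples.shape[:2]
        if T != self.sampling.n_frames:
            raise ValueError("frame count mismatch with sampling pattern")
        if n_kz != self.sampling.n_sampled_partitions:
            raise ValueError("kz axis inconsistent with sampling pattern")


def hybrid_decode(data: KSpaceData) -> np.ndarray:
    """Per-frame inverse DFT along the sampled kz comb.

    Returns hybrid data of shape (n_groups, T, readout, n_coils) with
    n_groups = Nz/R.  Group g superposes the R true slices z = g + r*Nz/R
    weighted by the CAIPIRINHA phases exp(-2i*pi*o(t)*r/R) / sqrt(R).  The
    additional common phase exp(-2i*pi*o(t)*g/Nz) produced by the comb
    offset is removed here, so downstream operators see exactly the T x R
    replicate phase matrix of :func:`stackmrf.sampling.caipi_phase`.  The
    transform is unitary (sample energy is preserved).
    """
    s = data.sampling
    R, Nz = s.reduction_factor, s.n_partitions
    M = s.n_sampled_partitions
    kz = np.asarray(s.kz_indices)
    if np.any(np.diff(kz, axis=1) != R):
        raise ValueError("kz sampling must be a uniform comb within each frame")
    # unitary inverse DFT over the comb index m for every frame at once
    decoded = np.fft.ifft(data.samples, axis=1) * np.sqrt(M)
    offsets = kz[:, 0] % R
    g = np.arange(M)
    correction = np.exp(2j * np.pi * offsets[:, None] * g[None, :] / Nz)
    decoded = decoded * correction[:, :, None, None]
    return np.ascontiguousarray(np.moveaxis(decoded, 1, 0))


class FusedSubspaceGridding:
    """Subspace expansion fused with gridding for a whole spoke train.

    Maps K coefficient images (K, N, N) to the stacked radial samples of
    all T frames (T * readout,).  The per-frame basis weights are folded
    into the sample-indexed weight table so an application needs only K
    oversampled FFTs and one sparse interpolation product, independent of
    T.  Numerically identical (to ~1e-6) to expanding the K coefficients to
    T frames and gridding each frame separately (:meth:`apply_unfused`).
    """

    def __init__(
        self,
        basis: np.ndarray,
        sampling: KTSampling,
        im_size: int,
        width: int = 8,
    ):
        basis = np.asarray(basis)
        if basis.shape[0] != sampling.n_frames:
            raise ValueError("basis rows must equal the number of frames")
        self.basis = basis
        self.rank = basis.shape[1]
        self.sampling = sampling
        self.n_readout = sampling.readout_samples
        points = np.concatenate(
            [spoke_coordinates(sampling, t) for t in range(sampling.n_frames)]
        )
        self.points = points
        self.plan = NufftPlan(points, im_size, width=width)
        self.n_samples = points.shape[0]
        # per-sample basis weights: frame of sample s is s // readout
        frames = np.arange(self.n_samples) // self.n_readout
        self.weights = basis[frames, :]  # (n_samples, K)
        self._interp_h = self.plan.interp.T.tocsr()  # real kernel: T == H

    @property
    def im_size(self) -> int:
        return self.plan.im_size

    def apply(self, coeff_images: np.ndarray) -> np.ndarray:
        """(K, N, N) coefficient images -> (T * readout,) samples."""
        if coeff_images.shape != (self.rank, self.im_size, self.im_size):
            raise ValueError("coefficient image stack has wrong shape")
        grids = np.stack([self.plan.to_grid(c) for c in coeff_images], axis=1)
        interp = self.plan.interp @ grids  # (n_samples, K)
        return np.einsum("sk,sk->s", interp, self.weights)

    def apply_batch(self, coeff_images: np.ndarray) -> np.ndarray:
        """(B, K, N, N) -> (n_samples, B), sharing one sparse product."""
        B = coeff_images.shape[0]
        grids = np.stack(
            [self.plan.to_grid(c) for img in coeff_images for c in img], axis=1
        )
        interp = self.plan.interp @ grids  # (n_samples, B*K)
        interp = interp.reshape(self.n_samples, B, self.rank)
        return np.einsum("sbk,sk->sb", interp, self.weights)

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact adjoint: (T * readout,) -> (K, N, N)."""
        return self.adjoint_batch(np.asarray(samples)[:, None])[0]

    def adjoint_batch(self, samples: np.ndarray) -> np.ndarray:
        """(n_samples, B) -> (B, K, N, N)."""
        B = samples.shape[1]
        weighted = samples[:, :, None] * np.conj(self.weights)[:, None, :]
        grids = self._interp_h @ weighted.reshape(self.n_samples, B * self.rank)
        out = np.stack([self.plan.from_grid(g) for g in grids.T])
        return out.reshape(B, self.rank, self.im_size, self.im_size)

    def apply_unfused(self, coeff_images: np.ndarray) -> np.ndarray:
        """Reference path: expand to T frames, then grid frame by frame."""
        n_read = self.n_readout
        out = np.empty(self.n_samples, dtype=complex)
        grids = np.stack([self.plan.to_grid(c) for c in coeff_images])  # (K, G^2)
        for t in range(self.sampling.n_frames):
            frame_grid = np.tensordot(self.basis[t], grids, axes=(0, 0))
            rows = self.plan.interp[t * n_read : (t + 1) * n_read]
            out[t * n_read : (t + 1) * n_read] = rows @ frame_grid
        return out


def combine_gridding_with_subspace(
    subspace: TemporalSubspace, sampling: KTSampling, im_size: int, width: int = 8
) -> FusedSubspaceGridding:
    """Fuse the temporal basis with the spoke-train gridding operator."""
    return FusedSubspaceGridding(subspace.basis, sampling, im_size, width=width)


class SliceGroupSystem:
    """Forward model and exact adjoint for one aliased slice group.

    ``forward`` maps coefficients (R, K, N, N) to hybrid-space samples
    (T * readout, n_coils); ``adjoint`` is its conjugate transpose.  The
    coil maps passed in must already be restricted to the group's R true
    slice positions.
    """

    def __init__(
        self,
        fused: FusedSubspaceGridding,
        coil_maps: np.ndarray,  # (n_coils, R, N, N)
        sampling: KTSampling,
    ):
        R = sampling.reduction_factor
        if coil_maps.ndim != 4 or coil_maps.shape[1] != R:
            raise ValueError("coil maps must be (n_coils, R, N, N)")
        if coil_maps.shape[2] != fused.im_size:
            raise ValueError("coil map grid does not match the operator grid")
        if not np.all(np.isfinite(coil_maps)):
            raise ValueError("non-finite coil maps")
        self.fused = fused
        self.coil_maps = coil_maps
        self.n_coils = coil_maps.shape[0]
        self.R = R
        phases = caipi_phase(sampling).phase  # (T, R)
        frames = np.arange(fused.n_samples) // fused.n_readout
        self.sample_phase = phases[frames, :]  # (n_samples, R)
        self.scale = 1.0 / np.sqrt(R)

    @property
    def alpha_shape(self) -> tuple[int, int, int, int]:
        return (self.R, self.fused.rank, self.fused.im_size, self.fused.im_size)

    def forward(self, alpha: np.ndarray) -> np.ndarray:
        if alpha.shape != self.alpha_shape:
            raise ValueError(f"alpha must have shape {self.alpha_shape}")
        if not np.all(np.isfinite(alpha)):
            raise ValueError("non-finite coefficient input")
        y = np.zeros((self.fused.n_samples, self.n_coils), dtype=complex)
        for r in range(self.R):
            weighted = self.coil_maps[:, r, None, :, :] * alpha[r][None]  # (C,K,N,N)
            y_r = self.fused.apply_batch(weighted)  # (n_samples, C)
            y += self.sample_phase[:, r, None] * y_r
        return y * self.scale

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        if y.shape != (self.fused.n_samples, self.n_coils):
            raise ValueError("data must have shape (n_samples, n_coils)")
        alpha = np.empty(self.alpha_shape, dtype=complex)
        for r in range(self.R):
            y_r = np.conj(self.sample_phase[:, r, None]) * y * self.scale
            imgs = self.fused.adjoint_batch(y_r)  # (C, K, N, N)
            alpha[r] = np.sum(
                np.conj(self.coil_maps[:, r, None, :, :]) * imgs, axis=0
            )
        return alpha

    def normal(self, alpha: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(alpha))

    def make_preconditioner(self, rho: float = 0.0):
        """Block-circulant approximate inverse of (E^H E + rho I).

        The normal operator of radial subspace sampling is, to good
        approximation, convolutional per replicate with a K x K coupling
        between coefficient channels at each spatial frequency: sample s at
        frequency u contributes the outer product of its basis-weight
        vector.  With unit-SOS coils and unit-modulus CAIPIRINHA phases the
        coil and replicate factors drop out of the approximation.  The
        returned callable applies, per replicate, FFT -> per-frequency
        inverse of (scale * H(u) + rho I) -> inverse FFT.  It is used only
        to precondition CG; the least-squares solution is unchanged.
        """
        fused = self.fused
        N = fused.im_size
        G = 2 * N
        K = fused.rank
        # exact Toeplitz spectrum: the normal operator acts, on the 2N
        # embedding grid, as a per-frequency K x K matrix H(u) equal to the
        # FFT of the point-spread kernel h_kl(d) = sum_s conj(w_k) w_l
        # exp(2i pi k_s . d); h is evaluated with the adjoint NUFFT on a
        # 2N image (displacements d span (-N, N))
        w = fused.weights  # (n_samples, K)
        plan2 = NufftPlan(fused.points, G, width=fused.plan.width)
        H = np.empty((G * G, K, K), dtype=complex)
        for k in range(K):
            for l in range(k, K):
                kern = plan2.adjoint(np.conj(w[:, k]) * w[:, l])
                spec = np.fft.fft2(np.fft.ifftshift(kern))
                H[:, k, l] = spec.reshape(-1)
                if l != k:
                    H[:, l, k] = np.conj(spec).reshape(-1)
        H = 0.5 * (H + np.conj(np.transpose(H, (0, 2, 1))))  # enforce Hermitian
        # calibrate the overall scale against the true normal operator
        rng = np.random.default_rng(0)
        x = rng.standard_normal(self.alpha_shape) + 1j * rng.standard_normal(
            self.alpha_shape
        )
        num = np.vdot(x, self.normal(x)).real
        lo = G // 2 - N // 2
        xp = np.zeros((self.R, K, G, G), dtype=complex)
        xp[:, :, lo : lo + N, lo : lo + N] = x
        xh = np.fft.fft2(xp, axes=(-2, -1)).reshape(self.R, K, G * G)
        den = np.einsum("rkf,fkl,rlf->", np.conj(xh), H, xh).real / (G * G)
        scale = num / max(den, 1e-30)
        # SPD floor keeps unsampled frequencies invertible at rho = 0
        floor = rho + 1e-3 * scale * np.mean(
            np.trace(H, axis1=1, axis2=2).real
        ) / K
        # kernel-approximation error leaves small negative eigenvalues in
        # the embedded spectrum; clip them so the preconditioner is SPD
        evals, evecs = np.linalg.eigh(H)
        inv_evals = 1.0 / (scale * np.maximum(evals, 0.0) + floor)
        Minv = np.einsum(
            "fkl,fl,fml->fkm", evecs, inv_evals, np.conj(evecs)
        )  # (G^2, K, K)

        def apply(alpha: np.ndarray) -> np.ndarray:
            padded = np.zeros((self.R, K, G, G), dtype=complex)
            padded[:, :, lo : lo + N, lo : lo + N] = alpha
            f = np.fft.fft2(padded, axes=(-2, -1)).reshape(self.R, K, G * G)
            g = np.einsum("fkl,rlf->rkf", Minv, f).reshape(self.R, K, G, G)
            out = np.fft.ifft2(g, axes=(-2, -1))
            return np.ascontiguousarray(out[:, :, lo : lo + N, lo : lo + N])

        return apply


def estimate_sensitivities(
    calibration_images: np.ndarray | None = None,
    ground_truth: CoilSensitivities | None = None,
    smooth_sigma: float = 2.0,
    support_threshold: float = 0.05,
) -> CoilSensitivities:
    """Coil sensitivity maps from calibration images, or ground-truth bypass.

    The calibration path is a simplified smoothed-ratio estimate: each coil
    image is low-pass filtered and divided by the root-sum-of-squares over
    coils, yielding smooth unit-SOS maps correct up to one global per-pixel
    phase (the phase of the underlying object).  Pixels below
    ``support_threshold`` of the peak RSS are zeroed.  In simulated mode,
    passing ``ground_truth`` returns the generator's maps unchanged.
    """
    if ground_truth is not None:
        return ground_truth
    if calibration_images is None:
        raise ValueError("need calibration images or ground-truth maps")
    imgs = np.asarray(calibration_images, dtype=complex)
    if imgs.ndim == 3:  # single-slice convenience: (C, N, N)
        imgs = imgs[:, None]
    if imgs.ndim != 4 or imgs.shape[0] < 1:
        raise ValueError("calibration images must be (n_coils, Nz, N, N)")
    if smooth_sigma > 0:
        sm = scipy.ndimage.gaussian_filter(
            imgs.real, sigma=(0, 0, smooth_sigma, smooth_sigma)
        ) + 1j * scipy.ndimage.gaussian_filter(
            imgs.imag, sigma=(0, 0, smooth_sigma, smooth_sigma)
        )
    else:
        sm = imgs
    rss = np.sqrt(np.sum(np.abs(sm) ** 2, axis=0))
    support = rss > support_threshold * rss.max()
    maps = np.zeros_like(sm)
    maps[:, support] = sm[:, support] / rss[support]
    return CoilSensitivities(maps=maps)
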