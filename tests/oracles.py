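"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the Bloch simulator
integrates individual dephasing isochromats, and the Fourier oracles
evaluate dense DFT sums directly.
"""

from __future__ import annotations

import numpy as np


def isochromat_fingerprint(
    flip_deg: np.ndarray,
    tr_ms: float,
    te_ms: float,
    t1_ms: float,
    t2_ms: float,
    inversion_efficiency: float = 1.0,
    recovery_delay_ms: float = 3000.0,
    n_cycles: int = 3,
    n_spins: int = 200,
) -> np.ndarray:
    """Brute-force FISP MRF signal from uniformly dephased isochromats.

    Each of ``n_spins`` spins accrues a fixed extra phase 2*pi*i/n_spins
    from the unbalanced spoiler gradient once per TR (after the echo); the
    reported signal is the complex mean of Mx + i*My at the echo time.
    RF pulses rotate about the x axis.
    """
    flip = np.deg2rad(np.asarray(flip_deg, dtype=float))
    T = flip.size
    phis = 2 * np.pi * np.arange(n_spins) / n_spins

    def rot_x(a):
        return np.array(
            [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
        )

    def relax(M, dt):
        e1, e2 = np.exp(-dt / t1_ms), np.exp(-dt / t2_ms)
        M = M * np.array([e2, e2, e1])[None, :]
        M[:, 2] += 1.0 - e1
        return M

    def dephase(M):
        c, s = np.cos(phis), np.sin(phis)
        Mx = c * M[:, 0] - s * M[:, 1]
        My = s * M[:, 0] + c * M[:, 1]
        return np.stack([Mx, My, M[:, 2]], axis=1)

    M = np.zeros((n_spins, 3))
    M[:, 2] = 1.0
    signal = np.zeros(T, dtype=complex)
    for _ in range(n_cycles):
        if inversion_efficiency > 0:
            M[:, 2] *= -inversion_efficiency
        for t in range(T):
            M = M @ rot_x(flip[t]).T
            M = relax(M, te_ms)
            signal[t] = np.mean(M[:, 0] + 1j * M[:, 1])
            M = relax(M, tr_ms - te_ms)
            M = dephase(M)
        M = relax(M, recovery_delay_ms)
    return signal


def dense_nufft(image: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Direct evaluation of (1/N) sum_x img(x) e^{-2i pi k.x}, x centered."""
    n = image.shape[0]
    coords = np.arange(n) - n // 2
    x, y = np.meshgrid(coords, coords, indexing="ij")
    out = np.empty(points.shape[0], dtype=complex)
    for i, (kx, ky) in enumerate(points):
        out[i] = np.sum(image * np.exp(-2j * np.pi * (kx * x + ky * y))) / n
    return out


def dense_forward_matrix(basis, sampling, coil_maps, phases):
    """Explicit matrix of the slice-group forward model on a tiny problem.

    Rows: samples flattened (frame-major, then readout) x coils appended
    as trailing axis handled by the caller; here we return a matrix of
    shape (n_samples * n_coils, R * K * N * N) built entry by entry from
    the model definition: per replicate, coil weighting, subspace
    expansion, centered DFT on the frame's spoke, CAIPIRINHA phase, and a
    1/sqrt(R) replicate-summation scale.
    """
    from stackmrf.sampling import spoke_coordinates

    n_coils, R, n, _ = coil_maps.shape
    T, K = basis.shape
    n_read = sampling.readout_samples
    coords = np.arange(n) - n // 2
    gx, gy = np.meshgrid(coords, coords, indexing="ij")
    n_samples = T * n_read
    mat = np.zeros((n_samples * n_coils, R * K * n * n), dtype=complex)
    for t in range(T):
        pts = spoke_coordinates(sampling, t)
        for s_i in range(n_read):
            kx, ky = pts[s_i]
            dft = np.exp(-2j * np.pi * (kx * gx + ky * gy)) / n  # (N, N)
            for c in range(n_coils):
                row = (t * n_read + s_i) * n_coils + c
                for r in range(R):
                    w = phases[t, r] / np.sqrt(R)
                    enc = w * dft * coil_maps[c, r]  # (N, N)
                    for k in range(K):
                        col0 = ((r * K) + k) * n * n
                        mat[row, col0 : col0 + n * n] += (
                            basis[t, k] * enc
                        ).ravel()
    return mat


def welford_stats(values: np.ndarray) -> tuple[float, float]:
    """Streaming mean and sample SD (independent of numpy's reductions)."""
    mean, m2, count = 0.0, 0.0, 0
    for v in np.asarray(values, dtype=float).ravel():
        count += 1
        delta = v - mean
        mean += delta / count
        m2 += delta * (v - mean)
    sd = (m2 / (count - 1)) ** 0.5 if count > 1 else 0.0
    return mean, sd
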