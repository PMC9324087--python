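"""Forward-model operators: hybrid decode, fused gridding, adjoint pairs."""

import numpy as np
import pytest

import stackmrf as sm
from stackmrf.operators import (
    FusedSubspaceGridding,
    KSpaceData,
    SliceGroupSystem,
    estimate_sensitivities,
    hybrid_decode,
)
from stackmrf.phantom import (
    PhantomSpec,
    Sphere,
    rasterize_phantom,
    simulate_acquisition,
    simulate_coils,
)

from conftest import make_tiny_system
from oracles import dense_forward_matrix


# ---------------------------------------------------------------- decode


def _tiny_phantom(n=16, nz=4):
    return PhantomSpec(
        n=n, nz=nz, voxel_size_mm=(2, 2, 2),
        spheres=[
            Sphere(center=(1.5, 5, 6), radius=3, t1_ms=800, t2_ms=100),
            Sphere(center=(2.0, 11, 10), radius=2.5, t1_ms=400, t2_ms=50),
        ],
    )


def test_hybrid_decode_r1_returns_slice_spokes():
    """R=1, signal in one slice only: decoded group equals that slice's data."""
    n, nz, T = 16, 4, 8
    spec = PhantomSpec(
        n=n, nz=nz, voxel_size_mm=(2, 2, 2),
        spheres=[Sphere(center=(2, 8, 8), radius=1.4, t1_ms=800, t2_ms=100)],
    )
    seq = sm.SequenceParams.default(T)
    samp = sm.make_kt_sampling(T, nz, 1, readout_samples=2 * n)
    coils = simulate_coils(1, n, nz)
    data = simulate_acquisition(spec, seq, samp, coils)
    hyb = hybrid_decode(data)
    assert hyb.shape == (nz, T, 2 * n, 1)
    # slices without phantom content decode to (near) zero
    assert np.linalg.norm(hyb[0]) <= 1e-10 * np.linalg.norm(hyb[2])


def test_hybrid_decode_is_unitary():
    rng = np.random.default_rng(0)
    samp = sm.make_kt_sampling(6, 8, 2, readout_samples=12)
    y = rng.standard_normal((6, 4, 12, 3)) + 1j * rng.standard_normal((6, 4, 12, 3))
    data = KSpaceData(samples=y, sampling=samp)
    hyb = hybrid_decode(data)
    assert np.linalg.norm(hyb) == pytest.approx(np.linalg.norm(y), rel=1e-10)


def test_hybrid_decode_r2_phases_match_dft_oracle():
    """Signal confined to the second replicate alternates sign frame to frame."""
    n, nz, T = 16, 4, 6
    # phantom occupying only slice 3 = group 1, replicate 1 (3 = 1 + 1*2)
    spec = PhantomSpec(
        n=n, nz=nz, voxel_size_mm=(2, 2, 1),
        spheres=[Sphere(center=(3.0, 8, 8), radius=0.9, t1_ms=800, t2_ms=100)],
    )
    seq = sm.SequenceParams.default(T)
    samp = sm.make_kt_sampling(T, nz, 2, readout_samples=2 * n)
    coils = simulate_coils(1, n, nz)
    data = simulate_acquisition(spec, seq, samp, coils)
    hyb = hybrid_decode(data)
    phases = sm.caipi_phase(samp).phase  # (T, 2)
    # direct DFT oracle: group-1 decoded frame t = phase[t,1]/sqrt(2) * rho_3(t)
    from oracles import dense_nufft
    from stackmrf.sampling import spoke_coordinates

    truth = rasterize_phantom(spec)
    fp = sm.simulate_fingerprint(seq, 800, 100)
    img = truth["m0"][3].astype(complex)
    for t in range(T):
        rho = dense_nufft(img * fp[t], spoke_coordinates(samp, t))
        expect = phases[t, 1] / np.sqrt(2) * rho
        assert np.allclose(hyb[1, t, :, 0], expect, atol=1e-6 * np.abs(rho).max())


def test_nonuniform_kz_rejected():
    samp = sm.make_kt_sampling(4, 8, 2, readout_samples=4)
    samp.kz_indices = samp.kz_indices.copy()
    samp.kz_indices[0] = [0, 3, 4, 6]
    y = np.zeros((4, 4, 4, 1), dtype=complex)
    with pytest.raises(ValueError):
        hybrid_decode(KSpaceData(samples=y, sampling=samp))


# ------------------------------------------------------- forward / adjoint


def test_forward_of_zero_is_zero_and_linear():
    system, *_ , rng = make_tiny_system()
    z = np.zeros(system.alpha_shape, dtype=complex)
    assert np.all(system.forward(z) == 0)
    a = rng.standard_normal(system.alpha_shape) + 1j * rng.standard_normal(
        system.alpha_shape
    )
    c = 0.7 - 1.3j
    assert np.allclose(system.forward(c * a), c * system.forward(a), rtol=1e-12)


def test_forward_matches_dense_matrix_oracle():
    """N=16, T=8, K=2, R=2, 2 coils against the explicit model matrix."""
    system, basis, coil_maps, sampling, rng = make_tiny_system(
        n=16, nz=4, T=8, R=2, n_coils=2, K=2
    )
    phases = sm.caipi_phase(sampling).phase
    mat = dense_forward_matrix(basis, sampling, coil_maps, phases)
    a = rng.standard_normal(system.alpha_shape) + 1j * rng.standard_normal(
        system.alpha_shape
    )
    y_fast = system.forward(a).reshape(-1)  # (samples, coils) -> row-major
    y_dense = (mat @ a.reshape(-1)).reshape(-1)
    assert np.linalg.norm(y_fast - y_dense) / np.linalg.norm(y_dense) <= 1e-5


def test_adjoint_matches_dense_matrix_oracle():
    system, basis, coil_maps, sampling, rng = make_tiny_system(
        n=16, nz=4, T=8, R=2, n_coils=2, K=2
    )
    phases = sm.caipi_phase(sampling).phase
    mat = dense_forward_matrix(basis, sampling, coil_maps, phases)
    y = rng.standard_normal((system.fused.n_samples, 2)) + 1j * rng.standard_normal(
        (system.fused.n_samples, 2)
    )
    adj_fast = system.adjoint(y).reshape(-1)
    adj_dense = np.conj(mat).T @ y.reshape(-1)
    assert np.linalg.norm(adj_fast - adj_dense) / np.linalg.norm(adj_dense) <= 1e-5


def test_adjoint_of_zero_is_zero():
    system, *_ = make_tiny_system()
    y = np.zeros((system.fused.n_samples, system.n_coils), dtype=complex)
    assert np.all(system.adjoint(y) == 0)


@pytest.mark.parametrize("n", [16, 32])
@pytest.mark.parametrize("R", [1, 2])
@pytest.mark.parametrize("K", [1, 3, 5])
def test_dot_test_across_shapes(n, R, K):
    system, *_ , rng = make_tiny_system(n=n, nz=4, T=12, R=R, n_coils=2, K=K)
    x = rng.standard_normal(system.alpha_shape) + 1j * rng.standard_normal(
        system.alpha_shape
    )
    y = rng.standard_normal((system.fused.n_samples, 2)) + 1j * rng.standard_normal(
        (system.fused.n_samples, 2)
    )
    lhs = np.vdot(y, system.forward(x))
    rhs = np.vdot(system.adjoint(y), x)
    assert abs(lhs - rhs) / abs(lhs) <= 1e-5


def test_replicate_decomposition():
    """Content in one replicate produces phase[t,r] times its own NUFFT."""
    system, basis, coil_maps, sampling, rng = make_tiny_system(
        n=16, nz=4, T=8, R=2, n_coils=1, K=2, seed=4
    )
    a = np.zeros(system.alpha_shape, dtype=complex)
    a[1] = rng.standard_normal(a.shape[1:]) + 1j * rng.standard_normal(a.shape[1:])
    y = system.forward(a)
    single = system.fused.apply_batch(
        (coil_maps[:, 1, None, :, :] * a[1][None])
    )  # (samples, coils)
    expect = system.sample_phase[:, 1, None] * single / np.sqrt(2)
    assert np.allclose(y, expect, atol=1e-12 * np.abs(single).max())


# --------------------------------------------------------- fused operator


def test_fused_equals_unfused_path():
    system, *_ , rng = make_tiny_system(n=16, nz=4, T=10, R=1, n_coils=1, K=3)
    fused = system.fused
    c = rng.standard_normal((3, 16, 16)) + 1j * rng.standard_normal((3, 16, 16))
    fast = fused.apply(c)
    slow = fused.apply_unfused(c)
    assert np.linalg.norm(fast - slow) / np.linalg.norm(slow) <= 1e-6


def test_fused_rank_one_constant_basis_grids_temporal_mean():
    """K=1 with a constant basis column reduces to plain gridding scaled by

    the column value: every frame's samples are that scalar times the NUFFT
    of the single coefficient image on the frame's spoke.
    """
    n, T = 16, 6
    sampling = sm.make_kt_sampling(T, 2, 1, readout_samples=2 * n)
    w = 1.0 / np.sqrt(T)
    fused = FusedSubspaceGridding(np.full((T, 1), w, dtype=complex), sampling, n)
    rng = np.random.default_rng(0)
    img = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    out = fused.apply(img[None])
    for t in range(T):
        direct = fused.plan.forward(img)[t * 2 * n : (t + 1) * 2 * n]
        assert np.allclose(out[t * 2 * n : (t + 1) * 2 * n], w * direct)


def test_fused_touches_only_k_channels():
    """Structural contract: application cost scales with K, not T."""
    T, K = 512, 5
    sampling = sm.make_kt_sampling(T, 2, 1, readout_samples=8)
    rng = np.random.default_rng(0)
    basis = np.linalg.qr(rng.standard_normal((T, K)) + 0j)[0]
    fused = FusedSubspaceGridding(basis, sampling, 8)
    calls = {"n": 0}
    orig = fused.plan.to_grid

    def counting(img):
        calls["n"] += 1
        return orig(img)

    fused.plan.to_grid = counting
    fused.apply(np.zeros((K, 8, 8), dtype=complex))
    assert calls["n"] == K
    assert fused.weights.shape == (T * 8, K)


# ----------------------------------------------------------- sensitivities


def test_single_coil_constant_calibration():
    maps = estimate_sensitivities(np.ones((1, 2, 8, 8), dtype=complex))
    assert np.allclose(np.abs(maps.maps), 1.0)


def test_ground_truth_bypass_returns_input():
    truth = simulate_coils(4, 16, 2)
    out = estimate_sensitivities(ground_truth=truth)
    assert out is truth


def test_smooth_maps_recovered_up_to_voxel_phase():
    """Coil images of a smooth object yield maps with unit SOS and correct

    relative coil structure (ratios between coils are phase-exact).
    """
    n, nz = 32, 2
    truth = simulate_coils(4, n, nz)
    xx, yy = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2, indexing="ij")
    obj = np.exp(-(xx**2 + yy**2) / (2 * (n / 4) ** 2)) * np.exp(
        0.3j * (xx + yy) / n
    )
    calib = truth.maps * obj[None, None]
    est = estimate_sensitivities(calib, smooth_sigma=1.0)
    support = np.abs(obj) > 0.2
    sos = np.sum(np.abs(est.maps[:, 0]) ** 2, axis=0)
    assert np.all(np.abs(sos[support] - 1.0) <= 0.05)
    # per-pixel phase cancels in coil ratios
    ratio_est = est.maps[1, 0][support] / est.maps[0, 0][support]
    ratio_true = truth.maps[1, 0][support] / truth.maps[0, 0][support]
    assert np.median(np.abs(ratio_est - ratio_true) / np.abs(ratio_true)) <= 0.05


def test_missing_calibration_rejected():
    with pytest.raises(ValueError):
        estimate_sensitivities()


def test_toeplitz_preconditioner_is_spd_and_preserves_the_solution():
    """The optional block-circulant preconditioner must be a valid SPD

    preconditioner: positive quadratic form, and preconditioned CG on the
    rho-shifted normal equations reaches the same solution as plain CG."""
    from stackmrf.solvers import _cg

    rng = np.random.default_rng(0)
    system, *_ = make_tiny_system(n=32, nz=4, T=64, R=1, n_coils=1, K=3, seed=0)
    system.coil_maps[:] = 1.0
    rho = 1e-2
    minv = system.make_preconditioner(rho)
    x = rng.standard_normal(system.alpha_shape) + 1j * rng.standard_normal(
        system.alpha_shape
    )
    assert np.vdot(x, minv(x)).real > 0  # SPD quadratic form
    y = system.forward(x)
    b = system.adjoint(y)
    b /= np.max(np.abs(b))
    A = lambda v: system.normal(v) + rho * v
    plain = _cg(A, b, np.zeros_like(b), 200, 1e-12)
    pcg = _cg(A, b, np.zeros_like(b), 200, 1e-12, apply_Minv=minv)
    assert np.linalg.norm(pcg - plain) / np.linalg.norm(plain) <= 1e-3
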