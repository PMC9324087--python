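"""CG least squares, the LLR proximal operator, and the ADMM solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stackmrf as sm
from stackmrf.solvers import ReconConfig, admm_llr_recon, cg_linear_recon, llr_norm, llr_prox

from conftest import make_tiny_system


# ----------------------------------------------------------------- CG


def test_cg_recovers_known_coefficients():
    """Noiseless consistent data on a small well-determined problem."""
    system, *_ , rng = make_tiny_system(n=16, nz=4, T=32, R=1, n_coils=3, K=2)
    a_true = rng.standard_normal(system.alpha_shape) + 1j * rng.standard_normal(
        system.alpha_shape
    )
    # smooth the truth so the radial system resolves it well
    import scipy.ndimage

    a_true = scipy.ndimage.gaussian_filter(a_true.real, (0, 0, 2, 2)) + \
        1j * scipy.ndimage.gaussian_filter(a_true.imag, (0, 0, 2, 2))
    y = system.forward(a_true)
    cfg = ReconConfig(cg_tolerance=1e-12)
    a_hat = cg_linear_recon(y, system, cfg, n_iters=50)
    assert np.linalg.norm(a_hat - a_true) / np.linalg.norm(a_true) <= 1e-4


def test_cg_zero_data_gives_zero():
    system, *_ = make_tiny_system()
    y = np.zeros((system.fused.n_samples, system.n_coils), dtype=complex)
    assert np.all(cg_linear_recon(y, system) == 0)


def test_cg_matches_dense_least_squares_oracle():
    """CG solution agrees with numpy.linalg.lstsq on the dense model matrix."""
    from oracles import dense_forward_matrix

    system, basis, coil_maps, sampling, rng = make_tiny_system(
        n=8, nz=4, T=16, R=2, n_coils=2, K=2, readout=16
    )
    mat = dense_forward_matrix(basis, sampling, coil_maps,
                               sm.caipi_phase(sampling).phase)
    a_true = rng.standard_normal(system.alpha_shape) + 1j * rng.standard_normal(
        system.alpha_shape
    )
    y = system.forward(a_true)
    lstsq = np.linalg.lstsq(mat, y.reshape(-1), rcond=None)[0]
    a_hat = cg_linear_recon(y, system, ReconConfig(cg_tolerance=1e-14),
                            n_iters=400)
    assert (
        np.linalg.norm(a_hat.reshape(-1) - lstsq) / np.linalg.norm(lstsq) <= 1e-3
    )


# ------------------------------------------------------------- llr_prox


def test_prox_threshold_zero_is_identity():
    rng = np.random.default_rng(0)
    a = rng.standard_normal((2, 3, 16, 16)) + 1j * rng.standard_normal((2, 3, 16, 16))
    assert np.array_equal(llr_prox(a, 0.0, 8), a)


def test_prox_full_shrinkage_zeroes_rank_one_patch():
    a = np.zeros((1, 2, 8, 8), dtype=complex)
    u = np.ones(64)
    a[0, 0] = u.reshape(8, 8)
    a[0, 1] = 2 * u.reshape(8, 8)
    s = np.linalg.norm([1.0, 2.0]) * np.linalg.norm(u)  # sole singular value
    out = llr_prox(a, s * 1.0001, 8)
    assert np.abs(out).max() <= 1e-10


def test_prox_equals_explicit_svd_soft_threshold():
    rng = np.random.default_rng(1)
    K, p, R = 4, 8, 2
    a = rng.standard_normal((R, K, p, p)) + 1j * rng.standard_normal((R, K, p, p))
    tau = 0.5
    out = llr_prox(a, tau, p)
    # independent dense computation on the single joint patch
    mat = np.transpose(a, (0, 2, 3, 1)).reshape(R * p * p, K)
    u, s, vh = np.linalg.svd(mat, full_matrices=False)
    ref = (u * np.maximum(s - tau, 0)) @ vh
    ref = np.transpose(ref.reshape(R, p, p, K), (0, 3, 1, 2))
    assert np.allclose(out, ref, atol=1e-10)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 1000), tau=st.floats(0.01, 2.0))
def test_prox_is_nonexpansive(seed, tau):
    rng = np.random.default_rng(seed)
    shape = (2, 3, 8, 8)
    a = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    b = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    d_out = np.linalg.norm(llr_prox(a, tau, 4) - llr_prox(b, tau, 4))
    assert d_out <= np.linalg.norm(a - b) + 1e-12


def test_prox_patch_size_must_divide_image():
    a = np.zeros((1, 2, 12, 12), dtype=complex)
    with pytest.raises(ValueError):
        llr_prox(a, 0.1, 8)


# ----------------------------------------------------------------- ADMM


def test_admm_with_zero_lambda_matches_unregularized_cg():
    """With the penalty off and a vanishing coupling, ADMM's x-updates

    solve the same least-squares problem as plain CG; compared once both
    are essentially converged on a smooth consistent problem."""
    import scipy.ndimage

    system, *_ , rng = make_tiny_system(n=16, nz=4, T=32, R=2, n_coils=3, K=2)
    a_true = rng.standard_normal(system.alpha_shape) + 1j * rng.standard_normal(
        system.alpha_shape
    )
    a_true = scipy.ndimage.gaussian_filter(a_true.real, (0, 0, 2, 2)) + \
        1j * scipy.ndimage.gaussian_filter(a_true.imag, (0, 0, 2, 2))
    y = system.forward(a_true)
    cfg = ReconConfig(lambda_llr=0.0, admm_rho=1e-8, n_admm_iters=20,
                      n_cg_iters=15, patch_size=8)
    admm = admm_llr_recon(y, system, cfg)
    cg = cg_linear_recon(y, system, ReconConfig(), n_iters=120)
    assert np.linalg.norm(admm - cg) / np.linalg.norm(cg) <= 1e-3


def test_admm_zero_data_gives_zero():
    system, *_ = make_tiny_system()
    y = np.zeros((system.fused.n_samples, system.n_coils), dtype=complex)
    out = admm_llr_recon(y, system, ReconConfig(lambda_llr=1e-3))
    assert np.all(out == 0)


def test_negative_lambda_rejected():
    with pytest.raises(ValueError):
        ReconConfig(lambda_llr=-1.0)


def _objective(system, y, x, lam, patch):
    resid = system.forward(x) - y
    return np.vdot(resid, resid).real + lam * llr_norm(x, patch)


def test_admm_objective_inequalities():
    """Objective at the ADMM output is no worse than at zero or at the

    unregularized CG solution (plus its own penalty)."""
    import scipy.ndimage

    system, *_ , rng = make_tiny_system(n=16, nz=4, T=32, R=2, n_coils=3, K=2,
                                        seed=7)
    a_true = rng.standard_normal(system.alpha_shape) + 1j * rng.standard_normal(
        system.alpha_shape
    )
    a_true = scipy.ndimage.gaussian_filter(a_true.real, (0, 0, 1, 1)) + \
        1j * scipy.ndimage.gaussian_filter(a_true.imag, (0, 0, 1, 1))
    y = system.forward(a_true)
    y += 0.01 * np.linalg.norm(y) / np.sqrt(y.size) * (
        rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
    )
    scale = np.max(np.abs(system.adjoint(y)))
    lam = 1e-3 * scale  # on the solver's normalized scale the config value
    cfg = ReconConfig(lambda_llr=1e-3, n_admm_iters=25, n_cg_iters=8,
                      patch_size=8)
    x = admm_llr_recon(y, system, cfg)
    obj_admm = _objective(system, y, x, lam, 8)
    obj_zero = _objective(system, y, np.zeros_like(x), lam, 8)
    cg = cg_linear_recon(y, system, ReconConfig(), n_iters=40)
    obj_cg = _objective(system, y, cg, lam, 8)
    assert obj_admm <= obj_zero * (1 + 1e-12)
    assert obj_admm <= obj_cg * (1 + 1e-12)


def test_nuclear_norm_monotone_in_lambda():
    system, *_ , rng = make_tiny_system(n=16, nz=4, T=24, R=2, n_coils=2, K=2,
                                        seed=9)
    a_true = rng.standard_normal(system.alpha_shape) + 1j * rng.standard_normal(
        system.alpha_shape
    )
    y = system.forward(a_true)
    norms = []
    for lam in (1e-5, 1e-3, 1e-1):
        cfg = ReconConfig(lambda_llr=lam, n_admm_iters=6, n_cg_iters=5,
                          patch_size=8)
        x = admm_llr_recon(y, system, cfg)
        norms.append(llr_norm(x, 8))
    assert norms[0] >= norms[1] >= norms[2]
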