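"""Extended-phase-graph (EPG) simulation of the FISP MRF fingerprint.

The EPG formalism tracks the Fourier coefficients of the intra-voxel
magnetization distribution ("configuration states") under RF pulses,
relaxation, and gradient spoiling.  For an ideally spoiled FISP train the
unbalanced gradient advances every transverse state by one dephasing order
per TR, so with T pulses at most T+1 orders are ever populated and the
simulation is exact with a state buffer of that size.

State storage per (T1, T2) entry: three complex vectors over dephasing
order k >= 0:

* ``Fp[k]``  -- transverse state F(+k)
* ``Fm[k]``  -- conj(F(-k)) (the standard conjugate storage)
* ``Z[k]``   -- longitudinal state Z(k); Z[0] is ordinary Mz

One repetition is (inversion -> T frames -> recovery delay); the returned
fingerprint is the echo train of the last of ``n_repetitions_to_steady_cycle``
such cycles, so incomplete recovery between repetitions is part of the
signal model.  Within each TR the ordering is: RF pulse, relaxation to the
echo time, signal readout (the k=0 transverse state), relaxation over the
remaining TR, gradient dephasing.  The inversion is modeled as an
instantaneous Mz -> -efficiency * Mz.
"""

from __future__ import annotations

import numpy as np

from .sequence import SequenceParams

__all__ = ["simulate_fingerprint", "simulate_fingerprints"]


def _rf_matrix(alpha_rad: float) -> np.ndarray:
    """EPG transition matrix for an RF pulse of angle alpha about the x axis."""
    a = alpha_rad
    c2, s2 = np.cos(a / 2.0) ** 2, np.sin(a / 2.0) ** 2
    s, c = np.sin(a), np.cos(a)
    return np.array(
        [
            [c2, s2, -1j * s],
            [s2, c2, 1j * s],
            [-0.5j * s, 0.5j * s, c],
        ],
        dtype=complex,
    )


def _relax(states: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> None:
    """In-place relaxation over an interval: decay all states, regrow Z(0)."""
    states[:, 0, :] *= e2[:, None]
    states[:, 1, :] *= e2[:, None]
    states[:, 2, :] *= e1[:, None]
    states[:, 2, 0] += 1.0 - e1


def _dephase(states: np.ndarray) -> None:
    """Advance all transverse states by one dephasing order (in place).

    F(k) -> F(k+1) for every k, which in conjugate storage means Fp shifts
    up, Fm shifts down, and the new F(0) comes from the old F(-1).
    """
    states[:, 0, 1:] = states[:, 0, :-1]  # Fp up; top order truncated
    states[:, 0, 0] = np.conj(states[:, 1, 1])  # F(0) <- F(-1)
    states[:, 1, :-1] = states[:, 1, 1:]  # Fm down
    states[:, 1, -1] = 0.0


def simulate_fingerprints(
    seq: SequenceParams, t1_ms: np.ndarray, t2_ms: np.ndarray
) -> np.ndarray:
    """Simulate FISP MRF fingerprints for many (T1, T2) pairs at once.

    Parameters
    ----------
    seq : SequenceParams
    t1_ms, t2_ms : array-like, shape (n,)
        Relaxation times in milliseconds, voxelwise paired; requires
        ``t1 >= t2 > 0`` elementwise.

    Returns
    -------
    ndarray, complex, shape (n, T)
        Per-frame transverse signal at the echo time of the final
        repetition, for unit equilibrium magnetization.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float))
    if t1.shape != t2.shape or t1.ndim != 1:
        raise ValueError("t1_ms and t2_ms must be 1-D arrays of equal length")
    if np.any(t2 <= 0) or np.any(t1 <= 0):
        raise ValueError("relaxation times must be positive")
    if np.any(t2 > t1):
        raise ValueError("non-physical input: t2 must not exceed t1")

    n = t1.size
    T = seq.n_frames
    n_orders = T + 1  # exact for ideally spoiled FISP within one train
    alphas = np.deg2rad(seq.flip_angles_deg)

    e1_te = np.exp(-seq.te_ms / t1)
    e2_te = np.exp(-seq.te_ms / t2)
    rest = seq.tr_ms - seq.te_ms
    e1_rest = np.exp(-rest / t1)
    e2_rest = np.exp(-rest / t2)
    e1_delay = np.exp(-seq.recovery_delay_ms / t1)
    e2_delay = np.exp(-seq.recovery_delay_ms / t2)

    rf = np.stack([_rf_matrix(a) for a in alphas])  # (T, 3, 3)

    states = np.zeros((n, 3, n_orders), dtype=complex)
    states[:, 2, 0] = 1.0  # thermal equilibrium
    signal = np.empty((n, T), dtype=complex)

    for _ in range(seq.n_repetitions_to_steady_cycle):
        # inversion preparation: Mz -> -efficiency * Mz; efficiency 0 means
        # the pulse is absent (not saturation)
        if seq.inversion_efficiency > 0:
            states[:, 2, :] *= -seq.inversion_efficiency
        for t in range(T):
            states = np.einsum("ij,njk->nik", rf[t], states)
            _relax(states, e1_te, e2_te)
            signal[:, t] = states[:, 0, 0]
            _relax(states, e1_rest, e2_rest)
            _dephase(states)
        # free relaxation over the inter-repetition delay (no gradients)
        _relax(states, e1_delay, e2_delay)

    return signal


def simulate_fingerprint(seq: SequenceParams, t1_ms: float, t2_ms: float) -> np.ndarray:
    """Single-voxel fingerprint; see :func:`simulate_fingerprints`."""
    return simulate_fingerprints(seq, np.array([t1_ms]), np.array([t2_ms]))[0]
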