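"""MRF sequence definition: the variable flip-angle train and its timing.

An MR-fingerprinting acquisition plays out a train of T excitation pulses
with varying flip angles at a fixed short TR, preceded by an adiabatic
inversion.  Between repetitions of the train a long recovery delay lets the
longitudinal magnetization relax back toward equilibrium; because recovery
is incomplete, the signal of repetition n depends on the history of earlier
repetitions and the simulator cycles the train until the response settles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["SequenceParams", "default_flip_angle_pattern"]


def default_flip_angle_pattern(n_frames: int = 512) -> np.ndarray:
    """Piecewise-sinusoidal flip-angle train in degrees.

    Four half-sine lobes of equal length with peak amplitudes
    (60, 30, 45, 25) degrees::

        alpha[n] = A[lobe] * sin(pi * (n mod L) / L),   L = n_frames // 4

    This keeps all angles in [0, 60] degrees and gives the train the
    low-frequency amplitude modulation that makes distinct (T1, T2) pairs
    produce distinguishable fingerprints.  Any user-supplied pattern can be
    used instead; this is the package default used throughout the tests.
    """
    if n_frames < 4:
        raise ValueError("pattern needs at least 4 frames")
    lobe_len = n_frames // 4
    amps = (60.0, 30.0, 45.0, 25.0)
    angles = np.zeros(n_frames)
    for i in range(n_frames):
        lobe = min(i // lobe_len, 3)
        angles[i] = amps[lobe] * np.sin(np.pi * (i - lobe * lobe_len) / lobe_len)
    return np.maximum(angles, 0.0)  # guard rounding at lobe boundaries


@dataclass
class SequenceParams:
    """Timing and flip-angle train of an inversion-prepared FISP MRF sequence.

    Parameters
    ----------
    flip_angles_deg : array-like
        T flip angles in degrees, one per MRF frame, each in [0, 180].
    tr_ms : float
        Repetition time in milliseconds (default 12 ms).
    te_ms : float
        Echo time in milliseconds.  Defaults to TR/2 (FISP convention).
    inversion_efficiency : float
        Fraction of Mz inverted by the preparation pulse, in [0, 1].
    recovery_delay_ms : float
        Delay between repetitions of the train (default 3000 ms) during
        which magnetization relaxes freely.
    n_repetitions_to_steady_cycle : int
        Number of (inversion -> train -> delay) cycles simulated before the
        returned repetition, so incomplete recovery is reflected.
    """

    flip_angles_deg: np.ndarray
    tr_ms: float = 12.0
    te_ms: float | None = None
    inversion_efficiency: float = 1.0
    recovery_delay_ms: float = 3000.0
    n_repetitions_to_steady_cycle: int = 3

    def __post_init__(self) -> None:
        self.flip_angles_deg = np.asarray(self.flip_angles_deg, dtype=float)
        if self.flip_angles_deg.ndim != 1 or self.flip_angles_deg.size < 1:
            raise ValueError("flip_angles_deg must be a non-empty 1-D sequence")
        if np.any(self.flip_angles_deg < 0) or np.any(self.flip_angles_deg > 180):
            raise ValueError("flip angles must lie in [0, 180] degrees")
        if self.te_ms is None:
            self.te_ms = self.tr_ms / 2.0
        if not (self.tr_ms > self.te_ms >= 0):
            raise ValueError("need tr_ms > te_ms >= 0")
        if not (0.0 <= self.inversion_efficiency <= 1.0):
            raise ValueError("inversion_efficiency must be in [0, 1]")
        if self.recovery_delay_ms < 0:
            raise ValueError("recovery_delay_ms must be >= 0")
        if self.n_repetitions_to_steady_cycle < 1:
            raise ValueError("n_repetitions_to_steady_cycle must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(self.flip_angles_deg.size)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "flip_angles_deg": self.flip_angles_deg.tolist(),
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "inversion_efficiency": self.inversion_efficiency,
            "recovery_delay_ms": self.recovery_delay_ms,
            "n_repetitions_to_steady_cycle": self.n_repetitions_to_steady_cycle,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SequenceParams":
        return cls(**json.loads(Path(path).read_text()))

    @classmethod
    def default(cls, n_frames: int = 512) -> "SequenceParams":
        """The package's reference protocol: default train, TR 12 ms, 3 s delay."""
        return cls(flip_angles_deg=default_flip_angle_pattern(n_frames))
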