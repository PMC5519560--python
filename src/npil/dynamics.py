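"""Linear calcium dynamics shared by the deconvolution solver and the simulator.

A spike at frame ``t`` produces an instantaneous fluorescence increment that
decays geometrically with per-frame factor ``r = 1 - dt/tau``::

    c[t] = r * c[t-1] + n[t],    c[0] = n[0]

so ``c = P @ n`` where ``P`` is lower triangular with entries ``r**(i-j)`` and
``M = P^{-1}`` is lower bidiagonal (diagonal 1, subdiagonal ``-r``).  All hot
paths apply ``P`` and ``M`` as O(T) recursions rather than dense matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter


@dataclass(frozen=True)
class CalciumDynamicsParams:
    """Frame duration and indicator decay time constant, both in seconds.

    ``decay_factor`` is the per-frame fluorescence retention
    ``r = 1 - frame_duration / time_constant`` and must lie in [0, 1).
    """

    frame_duration: float
    time_constant: float

    def __post_init__(self) -> None:
        if not (self.frame_duration > 0):
            raise ValueError("frame_duration must be positive")
        if not (self.time_constant >= self.frame_duration):
            # tau == dt (r = 0, memoryless) is the degenerate but valid limit
            raise ValueError("time_constant must be at least the frame duration")

    @property
    def decay_factor(self) -> float:
        return 1.0 - self.frame_duration / self.time_constant

    @classmethod
    def from_frame_rate(cls, frame_rate: float, time_constant: float) -> "CalciumDynamicsParams":
        return cls(frame_duration=1.0 / frame_rate, time_constant=time_constant)


@dataclass(frozen=True)
class TransitionMatrices:
    """Dense ``M`` (calcium -> spikes) and ``P = M^{-1}`` (spikes -> calcium)."""

    M: np.ndarray
    P: np.ndarray

    @property
    def decay_factor(self) -> float:
        return -float(self.M[1, 0]) if self.M.shape[0] > 1 else 0.0


def build_transition_matrix(params: CalciumDynamicsParams, T: int) -> TransitionMatrices:
    """Build the T x T bidiagonal spike-extraction matrix and its inverse.

    The first row is [1, 0, ...] (calcium starts at zero before the record),
    so ``M`` is square and invertible; ``P`` is computed by forward
    substitution, giving the explicit Toeplitz form ``P[i, j] = r**(i-j)``.
    """
    if T < 2:
        raise ValueError(f"need at least 2 frames, got T={T}")
    r = params.decay_factor
    if not (0.0 <= r < 1.0):
        raise ValueError(f"decay factor r={r} outside [0, 1)")
    M = np.eye(T)
    idx = np.arange(1, T)
    M[idx, idx - 1] = -r
    # forward substitution on the identity: rows of P accumulate powers of r
    P = np.zeros((T, T))
    P[0, 0] = 1.0
    for i in range(1, T):
        P[i] = r * P[i - 1]
        P[i, i] = 1.0
    return TransitionMatrices(M=M, P=P)


def apply_P(r: float, n: np.ndarray, axis: int = 0) -> np.ndarray:
    """Calcium trace from spikes: O(T) IIR filter c[t] = r c[t-1] + n[t]."""
    return lfilter([1.0], [1.0, -r], n, axis=axis)


def apply_P_transpose(r: float, v: np.ndarray) -> np.ndarray:
    """``P.T @ v`` via the time-reversed recursion (1-D only)."""
    return lfilter([1.0], [1.0, -r], v[::-1])[::-1]


def apply_M(r: float, c: np.ndarray) -> np.ndarray:
    """Spikes from calcium: n[t] = c[t] - r c[t-1] with c[-1] = 0 (1-D)."""
    n = np.asarray(c, dtype=float).copy()
    n[1:] -= r * c[:-1]
    return n
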