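"""Baseline phase corrections: susceptibility model, drift, temporal filtering.

Breathing modulates the magnetic field around the heart, so even after
registration the phase images carry a respiration-correlated
susceptibility component that would alias directly into temperature.
During a heating-free learning period the registered phase of each pixel
is regressed (ordinary least squares) against the per-frame motion
coefficients from the PCA motion basis; during the intervention the
motion-predicted phase is subtracted from every incoming frame.

Two further corrections run per frame: a spatially uniform phase-drift
estimate (median of the phase difference over pixels known to stay
unheated) compensating slow scanner field drift, and a causal low-pass
Butterworth filter (default cutoff 0.14 Hz, order 2) applied pixelwise
to the temperature series — tissue temperature evolves slowly compared
with the ~1 s frame interval, so the filter removes noise without
distorting the heating curve.

Phase differences are unwrapped temporally per pixel assuming the
inter-frame change stays below pi (amply satisfied: even the fastest
heating moves the phase by well under a radian per frame).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, lfilter_zi

__all__ = [
    "SusceptibilityModel",
    "ButterworthState",
    "TemporalUnwrapper",
    "learn_phase_model",
    "correct_susceptibility",
    "estimate_drift",
    "make_filter",
    "lowpass_step",
]

DEFAULT_CUTOFF_HZ = 0.14
DEFAULT_ORDER = 2
DEFAULT_N_LEARN = 30


@dataclass
class SusceptibilityModel:
    """Per-pixel linear map from motion coefficients to phase.

    ``predicted_phase = intercept_map + sum_j coefficient_maps[j] * c_j``.
    The intercept map is the motion-free baseline phase and doubles as a
    reference-phase candidate.
    """

    intercept_map: np.ndarray
    coefficient_maps: np.ndarray  # (n_coeffs, H, W)
    n_learn: int

    @property
    def n_coeffs(self) -> int:
        return self.coefficient_maps.shape[0]

    def predict(self, coeffs: np.ndarray) -> np.ndarray:
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (self.n_coeffs,):
            raise ValueError(
                f"expected {self.n_coeffs} coefficients, got {coeffs.shape}"
            )
        return self.intercept_map + np.tensordot(coeffs, self.coefficient_maps, 1)


def learn_phase_model(
    registered_phases: np.ndarray, motion_coeffs: np.ndarray
) -> SusceptibilityModel:
    """Fit the susceptibility phase model on the learning frames.

    Parameters
    ----------
    registered_phases : ndarray (n_learn, H, W)
        Registered, temporally unwrapped phase of the learning frames.
    motion_coeffs : ndarray (n_learn, p)
        Motion-basis coefficients of the same frames.

    Notes
    -----
    The fit is an independent per-pixel OLS sharing one design matrix
    ``[1, c_1..c_p]``.  If the coefficients carry no variance (constant
    motion descriptors) the design is rank deficient and the model falls
    back to intercept-only with a warning.
    """
    phases = np.asarray(registered_phases, dtype=float)
    C = np.atleast_2d(np.asarray(motion_coeffs, dtype=float))
    if C.shape[0] != phases.shape[0]:
        raise ValueError("frame count mismatch between phases and coefficients")
    n, p = C.shape
    if n < p + 2:
        raise ValueError(f"need at least p+2={p + 2} learning frames, got {n}")
    X = np.column_stack([np.ones(n), C])
    H, W = phases.shape[1:]
    Y = phases.reshape(n, -1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "rank-deficient motion coefficients; falling back to intercept-only model",
            RuntimeWarning,
            stacklevel=2,
        )
        intercept = Y.mean(axis=0).reshape(H, W)
        return SusceptibilityModel(intercept, np.zeros((p, H, W)), n)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return SusceptibilityModel(
        beta[0].reshape(H, W), beta[1:].reshape(p, H, W), n
    )


def correct_susceptibility(
    phase: np.ndarray, coeffs: np.ndarray, model: SusceptibilityModel
) -> np.ndarray:
    """Subtract the motion-predicted susceptibility phase from one frame.

    Only the motion-dependent part (coefficient maps times coefficients)
    is removed; the intercept is left untouched so the corrected phase
    stays on the same baseline as the reference.  The operation is linear
    and *not* idempotent — applying it twice subtracts the prediction
    twice — so callers must apply it exactly once per frame.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (model.n_coeffs,):
        raise ValueError(
            f"expected {model.n_coeffs} coefficients, got {coeffs.shape}"
        )
    return phase - np.tensordot(coeffs, model.coefficient_maps, 1)


def estimate_drift(phase_diff: np.ndarray, stable_mask: np.ndarray) -> float:
    """Spatially uniform phase drift: median of ``phase_diff`` over a mask
    of pixels known to be unaffected by heating."""
    stable_mask = np.asarray(stable_mask, dtype=bool)
    if not stable_mask.any():
        raise ValueError("empty stable mask")
    return float(np.median(np.asarray(phase_diff, dtype=float)[stable_mask]))


@dataclass
class ButterworthState:
    """Per-pixel delay registers of a causal low-pass Butterworth IIR.

    The filter is normalised to unit DC gain; state is initialised on the
    first sample so that a constant input is reproduced exactly from the
    start.
    """

    b: np.ndarray
    a: np.ndarray
    zi_unit: np.ndarray  # lfilter_zi for a unit step
    cutoff_hz: float
    sampling_hz: float
    z: np.ndarray | None = None  # (order, H, W), lazily initialised

    def copy(self) -> "ButterworthState":
        return ButterworthState(
            self.b, self.a, self.zi_unit, self.cutoff_hz, self.sampling_hz,
            None if self.z is None else self.z.copy(),
        )


def make_filter(
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    sampling_hz: float = 1.0,
    order: int = DEFAULT_ORDER,
) -> ButterworthState:
    """Create the streaming low-pass filter state."""
    if not (sampling_hz > 2 * cutoff_hz):
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist {sampling_hz / 2} Hz"
        )
    b, a = butter(order, cutoff_hz, btype="low", fs=sampling_hz)
    return ButterworthState(b, a, lfilter_zi(b, a), cutoff_hz, sampling_hz)


def lowpass_step(
    state: ButterworthState, frame: np.ndarray
) -> tuple[ButterworthState, np.ndarray]:
    """One causal IIR update of every pixel (direct form II transposed).

    Streaming contract: the output for frame t depends only on frames
    <= t.  Returns the updated state and the filtered frame.
    """
    x = np.asarray(frame, dtype=float)
    if state.z is None:
        # warm start at the first sample: constant input -> constant output
        state.z = state.zi_unit[:, None, None] * x[None]
    elif state.z.shape[1:] != x.shape:
        raise ValueError("frame shape changed mid-stream")
    b, a, z = state.b, state.a, state.z
    y = b[0] * x + z[0]
    for i in range(1, len(b) - 1):
        z[i - 1] = b[i] * x + z[i] - a[i] * y
    z[-1] = b[-1] * x - a[-1] * y
    return state, y


class TemporalUnwrapper:
    """Streaming per-pixel temporal phase unwrapping.

    Tracks, for every pixel, the previous wrapped sample and the running
    unwrapped value; each new frame advances by the wrapped increment
    ``((phi_t - phi_{t-1} + pi) mod 2pi) - pi``, which is exact whenever
    the true inter-frame phase change stays within (-pi, pi).
    """

    def __init__(self) -> None:
        self._prev_wrapped: np.ndarray | None = None
        self._unwrapped: np.ndarray | None = None

    def update(self, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        if self._prev_wrapped is None:
            self._prev_wrapped = phase.copy()
            self._unwrapped = phase.copy()
        else:
            inc = np.mod(phase - self._prev_wrapped + np.pi, 2 * np.pi) - np.pi
            self._unwrapped = self._unwrapped + inc
            self._prev_wrapped = phase.copy()
        return self._unwrapped.copy()
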