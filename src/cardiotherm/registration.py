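"""In-plane motion estimation, image warping and PCA motion modelling.

Residual in-plane respiratory motion is estimated on magnitude images as
a dense optical-flow field, phase images are resampled ("registered") to
a fixed reference position with that field, and the per-frame fields
observed during a learning period are summarised by principal component
analysis.  The PCA serves two purposes: the leading components span the
(essentially one-dimensional) respiratory motion manifold, so projecting
a freshly estimated field onto them denoises it, and the projection
coefficients are the compact motion descriptors that drive the
susceptibility-phase model in :mod:`cardiotherm.baseline`.

Coordinate convention: arrays are indexed (row, col) = (y, x), 0-based,
pixel-centred.  A displacement field maps reference coordinates to the
sampling positions in the moving image, i.e. ``warp(moving, field)``
samples the moving image at ``(y + dy, x + dx)`` and returns it aligned
with the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.registration import optical_flow_ilk, optical_flow_tvl1

__all__ = [
    "MotionField",
    "MotionBasis",
    "estimate_flow",
    "warp",
    "warp_phase",
    "build_motion_basis",
    "project_motion",
    "reconstruct_motion",
]


@dataclass
class MotionField:
    """Dense per-pixel 2D displacement, in pixels."""

    dy: np.ndarray
    dx: np.ndarray
    frame_index: int = -1

    def __post_init__(self) -> None:
        self.dy = np.asarray(self.dy, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        if self.dy.shape != self.dx.shape:
            raise ValueError("dy and dx shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dy.shape

    def as_vector(self) -> np.ndarray:
        """Flatten to a single (2*H*W,) vector, dy block then dx block."""
        return np.concatenate([self.dy.ravel(), self.dx.ravel()])

    @classmethod
    def from_vector(cls, vec: np.ndarray, shape: tuple[int, int],
                    frame_index: int = -1) -> "MotionField":
        n = shape[0] * shape[1]
        return cls(vec[:n].reshape(shape), vec[n:].reshape(shape), frame_index)


def estimate_flow(
    moving: np.ndarray,
    reference: np.ndarray,
    smoothness: float = 1.0,
    method: str = "tvl1",
    frame_index: int = -1,
) -> MotionField:
    """Estimate the dense displacement field registering ``moving`` onto
    ``reference``.

    A variational optical-flow energy (intensity mismatch plus a
    smoothness penalty on the field gradient) is minimised coarse-to-fine.
    ``smoothness`` scales the regularisation relative to the data term;
    larger values give smoother fields.

    Parameters
    ----------
    moving, reference : ndarray (H, W)
        Non-negative magnitude images of identical shape.
    smoothness : float
        Relative weight of the smoothness term (> 0).
    method : {"tvl1", "ilk"}
        ``"tvl1"`` uses total-variation regularised flow; ``"ilk"`` uses
        iterative Lucas-Kanade (faster, window-based smoothing).

    Returns
    -------
    MotionField
        Field such that ``warp(moving, field)`` approximates ``reference``.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError(
            f"image shapes differ: {moving.shape} vs {reference.shape}"
        )
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    if not np.any(moving) or not np.any(reference):
        warnings.warn(
            "all-zero image: no gradient information, returning zero field",
            RuntimeWarning,
            stacklevel=2,
        )
        z = np.zeros_like(moving)
        return MotionField(z, z.copy(), frame_index)
    if method == "tvl1":
        # attachment is the data-term weight: scale it down as smoothness
        # goes up so `smoothness` behaves like a regularisation weight.
        v, u = optical_flow_tvl1(reference, moving, attachment=15.0 / smoothness)
    elif method == "ilk":
        radius = max(3, int(round(7 * smoothness)))
        v, u = optical_flow_ilk(reference, moving, radius=radius)
    else:
        raise ValueError(f"unknown flow method {method!r}")
    return MotionField(v, u, frame_index)


def _sample(image: np.ndarray, field: MotionField, order: int = 1) -> np.ndarray:
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]].astype(float)
    return map_coordinates(
        image, [yy + field.dy, xx + field.dx], order=order, mode="nearest"
    )


def warp(
    image: np.ndarray,
    field: MotionField,
    return_valid: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Resample ``image`` at the displaced coordinates (bilinear).

    Out-of-bounds samples take nearest-edge values; when ``return_valid``
    is True a boolean mask marking in-bounds samples is returned as well.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != field.shape:
        raise ValueError("image and field shapes differ")
    if not (np.all(np.isfinite(field.dy)) and np.all(np.isfinite(field.dx))):
        raise ValueError("non-finite displacement field")
    out = _sample(image, field)
    if not return_valid:
        return out
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]].astype(float)
    sy, sx = yy + field.dy, xx + field.dx
    valid = (
        (sy >= 0)
        & (sy <= image.shape[0] - 1)
        & (sx >= 0)
        & (sx <= image.shape[1] - 1)
    )
    return out, valid


def warp_phase(phase: np.ndarray, field: MotionField) -> np.ndarray:
    """Warp a wrapped phase image through its complex representation.

    Interpolating cos/sin and re-extracting the angle avoids artifacts at
    the +/-pi wrap; the result is again wrapped to (-pi, pi].
    """
    phase = np.asarray(phase, dtype=float)
    if phase.shape != field.shape:
        raise ValueError("phase and field shapes differ")
    c = _sample(np.cos(phase), field)
    s = _sample(np.sin(phase), field)
    return np.arctan2(s, c)


@dataclass
class MotionBasis:
    """PCA decomposition of a collection of motion fields.

    ``components`` has shape (n_components, 2*H*W); rows are orthonormal
    under the flattened per-pixel inner product and ordered by decreasing
    explained variance.
    """

    mean_vector: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray  # fractions of total variance
    shape: tuple[int, int]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def mean_field(self) -> MotionField:
        return MotionField.from_vector(self.mean_vector, self.shape)


def build_motion_basis(fields: list[MotionField], n_components: int = 2) -> MotionBasis:
    """Principal component analysis of vectorised motion fields.

    Requires at least ``n_components + 1`` fields.  Components are the
    right singular vectors of the centred data matrix, ordered by
    decreasing variance; explained variance is reported as a fraction of
    the total (zero for all components when the fields are identical).
    """
    if len(fields) < n_components + 1:
        raise ValueError(
            f"need at least n_components+1={n_components + 1} fields, got {len(fields)}"
        )
    shape = fields[0].shape
    X = np.stack([f.as_vector() for f in fields])
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD keeps full control over the degenerate (zero-variance) case.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(len(fields) - 1, 1)
    total = var.sum()
    if n_components > vt.shape[0]:
        raise ValueError("n_components exceeds available rank")
    frac = var[:n_components] / total if total > 0 else np.zeros(n_components)
    return MotionBasis(mean, vt[:n_components], frac, shape)


def project_motion(field: MotionField, basis: MotionBasis) -> np.ndarray:
    """Coefficients of ``field - mean_field`` on the basis components."""
    if basis.n_components == 0:
        raise ValueError("empty basis")
    if field.shape != basis.shape:
        raise ValueError("field and basis shapes differ")
    return basis.components @ (field.as_vector() - basis.mean_vector)


def reconstruct_motion(
    coeffs: np.ndarray, basis: MotionBasis, frame_index: int = -1
) -> MotionField:
    """Rank-limited reconstruction mean + sum_i coeffs[i] * component_i."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (basis.n_components,):
        raise ValueError("coefficient count mismatch")
    vec = basis.mean_vector + coeffs @ basis.components
    return MotionField.from_vector(vec, basis.shape, frame_index)
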