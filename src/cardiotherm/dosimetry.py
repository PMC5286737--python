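"""CEM43 thermal-dose accumulation, uncertainty correction and lesion metrics.

The thermal dose at a pixel converts its time-temperature history into
cumulative equivalent minutes at 43 degC:

    CEM43 = sum_t R(T)^(T(t) - 43) * dt[min],   R = 2 for T >= 43, 4^-1 ... ;

concretely the integrand used here is 2^(T-43) above 43 degC and
4^(T-43) below, and a constant exposure of 240 min at 43 degC — dose
240 equivalent minutes, normalised value 1 — is taken as the lethal
threshold for myocardium.

Because the temperature estimate is noisy, the accumulated dose is
corrected with the baseline temperature uncertainty sigma_T (measured
over the pre-ablation frames):

    TD_corrected = TD * exp(-0.5 * (ln(2) * sigma_T)^2)

which discounts the dose where the thermometry is unreliable; the factor
lies in (0, 1] so correction never increases dose.

The lesion is the 8-connected component of supra-threshold pixels around
the heating focus; its size is reported as the full extents along the
principal axes of the component's pixel coordinates, in mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "LETHAL_CEM43",
    "ThermalDoseMap",
    "LesionMeasure",
    "dose_step",
    "dose_correction_factor",
    "correct_dose",
    "lethal_mask",
    "lesion_dimensions",
]

logger = logging.getLogger(__name__)

#: equivalent minutes at 43 degC taken as the lethal exposure
LETHAL_CEM43 = 240.0


@dataclass
class ThermalDoseMap:
    """Cumulative CEM43 dose state.

    Attributes
    ----------
    cem43 : ndarray (H, W)
        Equivalent minutes at 43 degC; non-decreasing over updates.
    sigma_baseline : ndarray (H, W) or None
        Pre-ablation temperature uncertainty, degC.
    corrected : ndarray or None
        Uncertainty-corrected dose (filled by :func:`correct_dose`).
    """

    cem43: np.ndarray
    sigma_baseline: np.ndarray | None = None
    corrected: np.ndarray | None = None

    @classmethod
    def zeros(cls, shape: tuple[int, int],
              sigma_baseline: np.ndarray | None = None) -> "ThermalDoseMap":
        return cls(np.zeros(shape, dtype=float), sigma_baseline)

    @property
    def normalized(self) -> np.ndarray:
        """Dose in lethal-threshold units (1 = 240 CEM43)."""
        return self.cem43 / LETHAL_CEM43

    @property
    def normalized_corrected(self) -> np.ndarray:
        if self.corrected is None:
            raise ValueError("call correct_dose first")
        return self.corrected / LETHAL_CEM43


def _r_factor(t_abs: np.ndarray) -> np.ndarray:
    dT = t_abs - 43.0
    return np.where(dT >= 0, np.exp2(dT), np.power(4.0, dT))


def dose_step(dose: ThermalDoseMap, t_abs: np.ndarray, dt_s: float) -> ThermalDoseMap:
    """Accumulate one frame of thermal dose (causal rectangle rule).

    The current absolute temperature map ``t_abs`` (degC) is held over
    the interval ``dt_s`` seconds.  Streaming contract: the update
    depends only on the current state and frame.
    """
    if dt_s <= 0:
        raise ValueError(f"dt_s must be > 0, got {dt_s}")
    t_abs = np.asarray(t_abs, dtype=float)
    if not np.all(np.isfinite(t_abs)):
        raise ValueError("non-finite temperature map")
    if t_abs.shape != dose.cem43.shape:
        raise ValueError("temperature map shape mismatch")
    dose.cem43 += _r_factor(t_abs) * (dt_s / 60.0)
    return dose


def dose_correction_factor(sigma_t: np.ndarray | float) -> np.ndarray | float:
    """Uncertainty discount exp(-0.5 * (ln(2) * sigma_T)^2), in (0, 1]."""
    sigma_t = np.asarray(sigma_t, dtype=float)
    if np.any(sigma_t < 0):
        raise ValueError("sigma_T must be non-negative")
    out = np.exp(-0.5 * (np.log(2.0) * sigma_t) ** 2)
    return float(out) if out.ndim == 0 else out


def correct_dose(dose: ThermalDoseMap) -> np.ndarray:
    """Apply the sigma_T uncertainty correction pixelwise.

    Requires ``dose.sigma_baseline``; stores and returns the corrected
    map.  Never increases dose.
    """
    if dose.sigma_baseline is None:
        raise ValueError("sigma_baseline not set on this dose map")
    dose.corrected = dose.cem43 * dose_correction_factor(dose.sigma_baseline)
    return dose.corrected


def lethal_mask(
    dose_map: np.ndarray,
    threshold: float = 1.0,
    seed_point: tuple[int, int] | None = None,
    normalized: bool = False,
) -> np.ndarray:
    """Binary mask of the lethal lesion component.

    Parameters
    ----------
    dose_map : ndarray (H, W)
        Dose in equivalent minutes (or already normalised when
        ``normalized=True``).
    threshold : float
        Lethal level in normalised units (1.0 = 240 CEM43).
    seed_point : (row, col) or None
        The connected component (8-connectivity) containing — or, if
        none contains it, nearest to — this pixel is kept; other
        supra-threshold components are discarded and counted in the log.
        With no seed the largest component is kept.

    An empty mask is a valid outcome (ablation that produced no lesion).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    norm = np.asarray(dose_map, dtype=float)
    if not normalized:
        norm = norm / LETHAL_CEM43
    supra = norm >= threshold
    if not supra.any():
        return supra
    labels = measure.label(supra, connectivity=2)
    n_comp = labels.max()
    if n_comp > 1:
        logger.info("lethal region has %d components; keeping one", n_comp)
    if seed_point is not None:
        lab = labels[tuple(seed_point)]
        if lab == 0:
            yy, xx = np.nonzero(supra)
            d2 = (yy - seed_point[0]) ** 2 + (xx - seed_point[1]) ** 2
            lab = labels[yy[np.argmin(d2)], xx[np.argmin(d2)]]
    else:
        sizes = np.bincount(labels.ravel())[1:]
        lab = int(np.argmax(sizes)) + 1
    return labels == lab


@dataclass
class LesionMeasure:
    """Principal-axis extents of the lethal component."""

    largest_mm: float
    smallest_mm: float
    area_mm2: float
    centroid: tuple[float, float]  # (row, col), pixels

    def __post_init__(self) -> None:
        if not (self.largest_mm >= self.smallest_mm > 0):
            raise ValueError("expected largest >= smallest > 0 for a lesion")


def lesion_dimensions(
    mask: np.ndarray, pixel_spacing_mm: float
) -> LesionMeasure | None:
    """Measure the lesion along its principal axes.

    Pixel-centre coordinates of the mask are decomposed by PCA; the
    reported dimensions are the full extents (max minus min projection
    plus one pixel) along the major and minor axes, in mm.  Returns
    ``None`` for an empty mask — a distinguished "no lesion" result, not
    an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return None
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be > 0")
    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # principal axes of the pixel cloud; eigh returns ascending eigenvalues
    cov = centered.T @ centered / len(coords)
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs  # column 1 = major axis
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0  # + one pixel footprint
    minor, major = np.sort(extents)
    return LesionMeasure(
        largest_mm=float(major * pixel_spacing_mm),
        smallest_mm=float(minor * pixel_spacing_mm),
        area_mm2=float(mask.sum() * pixel_spacing_mm**2),
        centroid=(float(centroid[0]), float(centroid[1])),
    )
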