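"""PRFS temperature mapping and temporal stability statistics.

The proton resonance frequency of water protons shifts linearly with
temperature (coefficient alpha, approximately -0.01 ppm/degC).  In a
gradient-echo acquisition this shift accumulates as image phase over the
echo time, so the temperature change between a dynamic frame and a
reference frame is

    dT = (phi_t - phi_ref) * k,     k = 1 / (2*pi * gamma/2pi * alpha * B0 * TE)

with gamma/2pi the proton gyromagnetic ratio in Hz/T.  With the standard
negative alpha, k is negative: heating lowers the phase.

Thermometry precision is characterised per pixel by the temporal mean
(mu_T) and standard deviation (sigma_T) of the temperature series over a
heating-free window; pixels whose sigma_T exceeds a threshold (7 degC by
default) are excluded from region statistics as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PRFSParams",
    "TemperatureSeries",
    "RoiSummary",
    "prfs_constant",
    "temperature_map",
    "temperature_stats",
    "roi_summary",
]

#: sigma_T above which a pixel is considered unreliable, degC
DEFAULT_EXCLUSION_THRESHOLD = 7.0


@dataclass(frozen=True)
class PRFSParams:
    """Acquisition constants entering the PRFS temperature conversion.

    Parameters
    ----------
    gamma_over_2pi_hz_per_t : float
        Proton gyromagnetic ratio, Hz/T (42.58 MHz/T).
    alpha_ppm_per_degc : float
        PRF temperature coefficient, ppm/degC (negative for water).
    b0_tesla : float
        Static field strength, T.
    te_s : float
        Echo time, s.
    """

    gamma_over_2pi_hz_per_t: float = 42.58e6
    alpha_ppm_per_degc: float = -0.0094
    b0_tesla: float = 1.5
    te_s: float = 0.018

    def __post_init__(self) -> None:
        if not (self.te_s > 0):
            raise ValueError(f"te_s must be > 0, got {self.te_s}")
        if not (self.b0_tesla > 0):
            raise ValueError(f"b0_tesla must be > 0, got {self.b0_tesla}")
        if self.alpha_ppm_per_degc == 0:
            raise ValueError("alpha_ppm_per_degc must be nonzero")
        if self.gamma_over_2pi_hz_per_t == 0:
            raise ValueError("gamma_over_2pi_hz_per_t must be nonzero")

    @property
    def k(self) -> float:
        """Phase-to-temperature factor, degC/rad (signed; negative for water)."""
        return prfs_constant(self)


def prfs_constant(params: PRFSParams) -> float:
    """Return the signed PRFS conversion factor k in degC per radian.

    k = (2*pi * gamma/2pi * alpha * B0 * TE)^-1 with alpha converted from
    ppm/degC to 1/degC.  For the defaults (1.5 T, TE 18 ms) |k| is about
    14.73 degC/rad.
    """
    denom = (
        2.0
        * np.pi
        * params.gamma_over_2pi_hz_per_t
        * params.alpha_ppm_per_degc
        * 1e-6
        * params.b0_tesla
        * params.te_s
    )
    return 1.0 / denom


def temperature_map(
    corrected_phase: np.ndarray, ref_phase: np.ndarray, k: float
) -> np.ndarray:
    """Convert a (corrected, unwrapped) phase frame to a temperature change map.

    dT = (phi_t - phi_ref) * k, elementwise.
    """
    corrected_phase = np.asarray(corrected_phase, dtype=float)
    ref_phase = np.asarray(ref_phase, dtype=float)
    if corrected_phase.shape != ref_phase.shape:
        raise ValueError(
            f"phase shapes differ: {corrected_phase.shape} vs {ref_phase.shape}"
        )
    if not (np.all(np.isfinite(corrected_phase)) and np.all(np.isfinite(ref_phase))):
        raise ValueError("non-finite phase values")
    return (corrected_phase - ref_phase) * k


def temperature_stats(
    dT: np.ndarray, exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel temporal mean, standard deviation and exclusion mask.

    Parameters
    ----------
    dT : ndarray, shape (n_frames, H, W)
        Temperature-change series over a window of at least two frames.
    exclusion_threshold : float
        sigma_T level (degC) above which a pixel is flagged unreliable.

    Returns
    -------
    mu_map, sigma_map : ndarray (H, W)
        Sample mean and sample standard deviation (ddof=1) over time.
    exclusion_mask : ndarray of bool (H, W)
        True where sigma_map > exclusion_threshold.
    """
    dT = np.asarray(dT, dtype=float)
    if dT.ndim != 3 or dT.shape[0] < 2:
        raise ValueError("need a (n_frames, H, W) stack with n_frames >= 2")
    mu = dT.mean(axis=0)
    sigma = dT.std(axis=0, ddof=1)
    return mu, sigma, sigma > exclusion_threshold


@dataclass
class RoiSummary:
    """Region statistics of the stability maps, excluded pixels removed."""

    mean_sigma: float
    mean_mu: float
    fraction_excluded: float
    n_pixels: int
    n_excluded: int


def roi_summary(
    mu_map: np.ndarray,
    sigma_map: np.ndarray,
    exclusion_mask: np.ndarray,
    roi: np.ndarray,
) -> RoiSummary:
    """Summarise mu_T / sigma_T over a region of interest.

    Pixels flagged in ``exclusion_mask`` are removed from the means but
    counted in the excluded fraction, mirroring how unreliable pixels are
    dropped from myocardial ROI statistics.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    excl = np.asarray(exclusion_mask, dtype=bool) & roi
    keep = roi & ~excl
    n_roi = int(roi.sum())
    n_excl = int(excl.sum())
    if not keep.any():  # every ROI pixel excluded
        return RoiSummary(np.nan, np.nan, 1.0, n_roi, n_excl)
    return RoiSummary(
        mean_sigma=float(sigma_map[keep].mean()),
        mean_mu=float(mu_map[keep].mean()),
        fraction_excluded=n_excl / n_roi,
        n_pixels=n_roi,
        n_excluded=n_excl,
    )


@dataclass
class TemperatureSeries:
    """Temperature-change maps produced by the pipeline.

    Attributes
    ----------
    dT : ndarray (n_frames, H, W)
        Temporally low-pass filtered temperature change per frame, degC.
        Frames before ``valid_from`` belong to the learning stage and are
        zero.
    dT_raw : ndarray (n_frames, H, W)
        Unfiltered temperature change (same validity convention).
    t_ref : float
        Absolute reference (body) temperature, degC; T(t) = t_ref + dT.
    valid_from : int
        Index of the first frame with a defined temperature.
    mu_map, sigma_map : ndarray (H, W) or None
        Stability statistics over the heating-free window.
    exclusion_mask : ndarray of bool or None
        Pixels with sigma_map above the exclusion threshold.
    sigma_baseline : ndarray (H, W) or None
        sigma_T of the unfiltered series over the pre-ablation window used
        by the thermal-dose uncertainty correction.
    """

    dT: np.ndarray
    dT_raw: np.ndarray
    t_ref: float
    valid_from: int = 0
    mu_map: np.ndarray | None = None
    sigma_map: np.ndarray | None = None
    exclusion_mask: np.ndarray | None = None
    sigma_baseline: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.dT.shape[0]

    def absolute(self, frame: int) -> np.ndarray:
        """Absolute temperature map T = t_ref + dT for one frame."""
        return self.t_ref + self.dT[frame]
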