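"""Synthetic dynamic MR thermometry phantom with known ground truth.

Generates a 2D+time magnitude/phase series emulating a free-breathing
cardiac thermometry acquisition (one frame per cardiac cycle):

* a smooth, deterministic anatomy template (soft-edged disc with gentle
  texture so optical flow is well posed) translated rigidly in-plane by
  a sinusoidal respiratory displacement;
* a susceptibility phase component linear in the instantaneous
  displacement, with a per-pixel gain map (default: planar gradient
  across the field of view) — the same structure the learned correction
  model assumes;
* a spatially uniform, linear-in-time phase drift;
* a localized Gaussian heating focus whose amplitude follows an
  exponential rise during RF delivery and an exponential decay after,
  written into the phase with the same signed PRFS constant the
  thermometry stage uses;
* complex Gaussian noise (Rician magnitude statistics); at a tissue
  magnitude of 1 the phase noise standard deviation is ~1/SNR.

Tissue-attached contributions (anatomy phase, heating, susceptibility)
are composed in the tissue frame and warped together with the anatomy,
so the ground-truth maps live in the registered (reference) frame that
the pipeline reconstructs.  The drift, a scanner-wide field effect, is
added after warping.

Every field of the ground truth is stored, which makes the phantom the
independent oracle for the downstream stages: :func:`true_dose`
integrates the CEM43 integrand densely on the *true* temperature curve
and is the brute-force reference for the streaming dose accumulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .dosimetry import ThermalDoseMap
from .thermometry import PRFSParams

__all__ = [
    "PhantomConfig",
    "FrameSeries",
    "GroundTruth",
    "default_gain_map",
    "generate_series",
    "true_dose",
]


@dataclass
class FrameSeries:
    """Time-ordered 2D magnitude + phase frames (the pipeline input)."""

    magnitude: np.ndarray  # (n, H, W), arbitrary units
    phase: np.ndarray  # (n, H, W), rad, wrapped to (-pi, pi]
    timestamps: np.ndarray  # (n,), s
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        if len(self.timestamps) != self.magnitude.shape[0]:
            raise ValueError("timestamp count mismatch")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.magnitude.shape[1:]

    @property
    def frame_interval_s(self) -> float:
        if self.n_frames < 2:
            return 1.0
        return float(self.timestamps[1] - self.timestamps[0])


@dataclass
class GroundTruth:
    """Known truth underlying a generated series (reference frame)."""

    true_dT: np.ndarray  # (n, H, W), degC, >= 0
    true_motion_px: np.ndarray  # (n, 2) rigid displacement (dy, dx), px
    true_susceptibility_phase: np.ndarray  # (n, H, W), rad
    true_drift: np.ndarray  # (n,), rad
    frame_interval_s: float
    pixel_spacing_mm: float
    hotspot_yx: tuple[int, int]
    body_mask: np.ndarray  # (H, W) bool, tissue support
    heat_sigma_mm: float


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom acquisition and perturbation parameters.

    Defaults emulate the conditions of a monitored ventricular RF
    ablation: 0.8 mm reconstructed pixels, one frame per ~1 s cardiac
    cycle, breathing at 24 breaths/min with a 5 mm residual in-plane
    excursion, slow field drift worth ~5 degC over 2.5 min, and RF
    switched on at the 50th frame.

    ``susceptibility_gain_rad_per_mm`` may be a full (H, W) map; None
    selects the default planar gradient (0 to 0.1 rad/mm across the
    field of view).  ``snr`` is the tissue magnitude SNR; ``np.inf``
    disables noise.
    """

    grid_size: tuple[int, int] = (96, 96)
    pixel_spacing_mm: float = 0.8
    frame_interval_s: float = 1.0
    n_frames: int = 200
    resp_amplitude_mm: float = 5.0
    resp_rate_bpm: float = 24.0
    susceptibility_gain_rad_per_mm: np.ndarray | None = None
    drift_rate_rad_s: float = -0.00226  # ~ +5 degC over 150 s at default PRFS
    heat_peak_degc: float = 30.0
    heat_sigma_mm: float = 3.0
    heat_onset_frame: int = 49  # 0-based; default = the 50th frame
    heat_duration_frames: int = 60
    heat_rise_tau_s: float = 10.0
    heat_decay_tau_s: float = 20.0
    snr: float = 80.0
    seed: int = 0
    prfs: PRFSParams = field(default_factory=PRFSParams)

    def validate(self) -> None:
        positive = {
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "frame_interval_s": self.frame_interval_s,
            "heat_sigma_mm": self.heat_sigma_mm,
            "heat_rise_tau_s": self.heat_rise_tau_s,
            "heat_decay_tau_s": self.heat_decay_tau_s,
            "snr": self.snr,
        }
        for name, value in positive.items():
            if not (value > 0):
                raise ValueError(f"{name} must be > 0, got {value}")
        nonneg = {
            "resp_amplitude_mm": self.resp_amplitude_mm,
            "resp_rate_bpm": self.resp_rate_bpm,
            "heat_peak_degc": self.heat_peak_degc,
            "heat_onset_frame": self.heat_onset_frame,
            "heat_duration_frames": self.heat_duration_frames,
        }
        for name, value in nonneg.items():
            if not (value >= 0):
                raise ValueError(f"{name} must be >= 0, got {value}")
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")
        if not np.isfinite(self.drift_rate_rad_s):
            raise ValueError(f"drift_rate_rad_s must be finite, got {self.drift_rate_rad_s}")
        if self.n_frames < self.heat_onset_frame + 1:
            raise ValueError(
                f"n_frames ({self.n_frames}) must be >= heat_onset_frame+1 "
                f"({self.heat_onset_frame + 1})"
            )
        if self.susceptibility_gain_rad_per_mm is not None:
            g = np.asarray(self.susceptibility_gain_rad_per_mm)
            if g.shape != tuple(self.grid_size):
                raise ValueError("susceptibility_gain_rad_per_mm shape mismatch")
            if not np.all(np.isfinite(g)):
                raise ValueError("susceptibility_gain_rad_per_mm must be finite")


def default_gain_map(grid_size: tuple[int, int]) -> np.ndarray:
    """Planar susceptibility gain, 0 to ~0.1 rad per mm of displacement."""
    H, W = grid_size
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    return 0.05 + 0.05 * ((xx - W / 2) / W + (yy - H / 2) / H)


def _anatomy(grid_size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic magnitude template, anatomy phase and body mask.

    The template is a soft-edged disc at plateau 1 with low-frequency
    texture (gradients for optical flow) and a brighter myocardium-like
    annulus; outside the disc the signal drops to a small air level.
    """
    H, W = grid_size
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    cy, cx = (H - 1) / 2, (W - 1) / 2
    r = np.hypot(yy - cy, xx - cx)
    r0 = 0.40 * min(H, W)
    disc = 0.5 * (1 + np.tanh((r0 - r) / (0.04 * min(H, W))))
    texture = (
        1.0
        + 0.15 * np.sin(2 * np.pi * xx / W * 3.3) * np.cos(2 * np.pi * yy / H * 2.7)
        + 0.10 * np.sin(2 * np.pi * (xx + yy) / (H + W) * 7.1)
    )
    annulus = 0.25 * np.exp(-((r - 0.22 * min(H, W)) ** 2) / (2 * (0.05 * min(H, W)) ** 2))
    magnitude = 0.05 + disc * (texture + annulus - 0.05)
    phase = 0.4 * np.sin(2 * np.pi * xx / W * 1.3 + 0.7) * np.cos(2 * np.pi * yy / H * 1.1)
    return magnitude, phase, disc > 0.5


def _heating_envelope(t: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Temporal heating envelope in [0, 1): exponential rise then decay."""
    t_on = cfg.heat_onset_frame * cfg.frame_interval_s
    t_off = t_on + cfg.heat_duration_frames * cfg.frame_interval_s
    env = np.zeros_like(t)
    rising = (t >= t_on) & (t < t_off)
    env[rising] = 1.0 - np.exp(-(t[rising] - t_on) / cfg.heat_rise_tau_s)
    after = t >= t_off
    peak = 1.0 - np.exp(-(t_off - t_on) / cfg.heat_rise_tau_s)
    env[after] = peak * np.exp(-(t[after] - t_off) / cfg.heat_decay_tau_s)
    return env


def generate_series(config: PhantomConfig) -> tuple[FrameSeries, GroundTruth]:
    """Generate a synthetic series and its ground truth.

    Identical config and seed give bit-identical output; the seed only
    drives the noise, never the deterministic ground-truth components.
    """
    config.validate()
    H, W = config.grid_size
    rng = np.random.default_rng(config.seed)
    mag0, phase0, body = _anatomy(config.grid_size)
    gain = (
        np.asarray(config.susceptibility_gain_rad_per_mm, dtype=float)
        if config.susceptibility_gain_rad_per_mm is not None
        else default_gain_map(config.grid_size)
    )

    t = np.arange(config.n_frames) * config.frame_interval_s
    f_resp = config.resp_rate_bpm / 60.0
    disp_mm = config.resp_amplitude_mm * np.sin(2 * np.pi * f_resp * t)
    direction = np.array([0.894, 0.447])  # unit (dy, dx)
    motion_px = disp_mm[:, None] * direction[None] / config.pixel_spacing_mm

    env = _heating_envelope(t, config)
    cy, cx = (H - 1) / 2, (W - 1) / 2
    hotspot = (int(round(cy)), int(round(cx)))
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    sig_px = config.heat_sigma_mm / config.pixel_spacing_mm
    gauss = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig_px**2))

    k = config.prfs.k
    drift = config.drift_rate_rad_s * t
    noise_sigma = 0.0 if np.isinf(config.snr) else 1.0 / config.snr

    magnitude = np.empty((config.n_frames, H, W))
    phase = np.empty_like(magnitude)
    true_dT = np.empty_like(magnitude)
    true_sus = np.empty_like(magnitude)
    base_coords = np.mgrid[0:H, 0:W].astype(float)
    for i in range(config.n_frames):
        dT_i = config.heat_peak_degc * env[i] * gauss
        sus_i = gain * disp_mm[i]
        tissue_phase = phase0 + dT_i / k + sus_i
        # frame shows tissue displaced by +d: sample the template at x - d
        coords = [base_coords[0] - motion_px[i, 0], base_coords[1] - motion_px[i, 1]]
        m = map_coordinates(mag0, coords, order=1, mode="nearest")
        p = map_coordinates(tissue_phase, coords, order=1, mode="nearest") + drift[i]
        cplx = m * np.exp(1j * p)
        if noise_sigma > 0:
            cplx = cplx + noise_sigma * (
                rng.standard_normal((H, W)) + 1j * rng.standard_normal((H, W))
            )
        magnitude[i] = np.abs(cplx)
        phase[i] = np.angle(cplx)
        true_dT[i] = dT_i
        true_sus[i] = sus_i

    series = FrameSeries(magnitude, phase, t, config.pixel_spacing_mm)
    gt = GroundTruth(
        true_dT=true_dT,
        true_motion_px=motion_px,
        true_susceptibility_phase=true_sus,
        true_drift=drift,
        frame_interval_s=config.frame_interval_s,
        pixel_spacing_mm=config.pixel_spacing_mm,
        hotspot_yx=hotspot,
        body_mask=body,
        heat_sigma_mm=config.heat_sigma_mm,
    )
    return series, gt


def true_dose(
    gt: GroundTruth, t_ref: float = 37.0, fine_substeps: int = 1
) -> ThermalDoseMap:
    """Dense Riemann integration of the CEM43 integrand on the true
    temperature curve.

    The true dT is interpolated linearly in time between frames (held
    constant after the last frame); each frame interval is split into
    ``fine_substeps`` sub-intervals integrated with the left-endpoint
    rectangle rule.  With ``fine_substeps=1`` this reproduces the
    streaming accumulator exactly, so it serves as its brute-force
    oracle; large values converge to the exact integral.
    """
    if fine_substeps < 1:
        raise ValueError("fine_substeps must be >= 1")
    from .dosimetry import dose_step  # local import to avoid cycles at import time

    n = gt.true_dT.shape[0]
    dose = ThermalDoseMap.zeros(gt.true_dT.shape[1:])
    dt_sub = gt.frame_interval_s / fine_substeps
    for i in range(n):
        nxt = gt.true_dT[i + 1] if i + 1 < n else gt.true_dT[i]
        for j in range(fine_substeps):
            frac = j / fine_substeps
            T = t_ref + (1 - frac) * gt.true_dT[i] + frac * nxt
            dose_step(dose, T, dt_sub)
    return dose
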