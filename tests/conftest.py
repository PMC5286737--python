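"""Shared fixtures: small phantoms reused across the suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings
from scipy.ndimage import binary_erosion

import cardiotherm as ct

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def eroded_roi(body_mask: np.ndarray, iterations: int = 6) -> np.ndarray:
    """Tissue ROI away from the phantom edge (interpolation artifacts)."""
    return binary_erosion(body_mask, iterations=iterations)


@pytest.fixture(scope="session")
def clean_heated():
    """Noise/motion/drift-free heated phantom and its pipeline result."""
    cfg = ct.PhantomConfig(
        grid_size=(64, 64),
        n_frames=130,
        snr=np.inf,
        resp_amplitude_mm=0.0,
        drift_rate_rad_s=0.0,
        heat_peak_degc=30.0,
        heat_duration_frames=60,
    )
    series, gt = ct.generate_series(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # motionless: intercept-only
        result = ct.run_pipeline(series, ct.PipelineConfig())
    return cfg, series, gt, result


@pytest.fixture(scope="session")
def perturbed_heated():
    """Heated phantom with motion, susceptibility, drift and noise on."""
    cfg = ct.PhantomConfig(
        grid_size=(64, 64),
        n_frames=120,
        heat_peak_degc=60.0,
        heat_duration_frames=40,
        snr=100.0,
        seed=2,
    )
    series, gt = ct.generate_series(cfg)
    yy, xx = np.mgrid[0 : cfg.grid_size[0], 0 : cfg.grid_size[1]]
    far = (
        np.hypot(yy - gt.hotspot_yx[0], xx - gt.hotspot_yx[1])
        > 4 * gt.heat_sigma_mm / cfg.pixel_spacing_mm
    )
    pcfg = ct.PipelineConfig(drift_mask=far & gt.body_mask)
    result = ct.run_pipeline(series, pcfg)
    return cfg, series, gt, result
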