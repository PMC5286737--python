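"""End-to-end causal thermometry/dosimetry pipeline and report I/O.

Processing order per frame mirrors the acquisition-time chain:
register -> susceptibility-correct -> drift-correct -> PRFS convert ->
temporal filter -> dose accumulate.  The stream is strictly causal: the
output at frame t depends only on frames <= t, so truncating the input
series reproduces every earlier output exactly.

Stages of a run (frame indices 0-based; defaults in parentheses):

1. Learning, frames 0 .. n_learn-1 (30): optical flow of each magnitude
   frame against frame 0; PCA motion basis; per-pixel OLS of the
   registered, temporally unwrapped phase against the motion
   coefficients (the susceptibility model).
2. Baseline, frames n_learn .. rf_start-2: the reference phase is the
   causal running mean of the corrected phase over this window
   (averaging reduces reference noise); the per-pixel sigma_T of the
   *unfiltered* temperature over the last ``sigma_baseline_window``
   pre-RF frames (20) feeds the dose uncertainty correction.
3. Intervention, frames rf_start-1 .. end: temperature maps stream into
   the CEM43 accumulator; at the end the dose is uncertainty-corrected
   and the lethal lesion extracted and measured.

``rf_start_frame`` is 1-based ("RF starts at the 50th image" means the
first heated frame has index 49); ``rf_start_frame=None`` runs a
stability-only analysis (no dose), with the reference window fixed to
``ref_window_frames``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import baseline as bl
from . import dosimetry as dm
from . import registration as reg
from . import thermometry as th
from .phantom import FrameSeries

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "write_report",
    "save_series",
    "load_series",
]


@dataclass
class PipelineConfig:
    """Pipeline parameters.

    The invariant ``n_learn + sigma_baseline_window <= rf_start_frame``
    guarantees that model learning and the noise-baseline window both
    precede any heating.
    """

    prfs: th.PRFSParams = field(default_factory=th.PRFSParams)
    n_learn: int = 30
    sigma_baseline_window: int = 20
    rf_start_frame: int | None = 50  # 1-based index of the first RF image
    ref_window_frames: int = 19  # used when rf_start_frame is None
    cutoff_hz: float = bl.DEFAULT_CUTOFF_HZ
    filter_order: int = bl.DEFAULT_ORDER
    n_motion_components: int = 2
    flow_smoothness: float = 1.0
    flow_method: str = "tvl1"
    drift_mask: np.ndarray | None = None  # None: all pixels
    exclusion_threshold_degc: float = th.DEFAULT_EXCLUSION_THRESHOLD
    t_ref_degc: float = 37.0
    lethal_threshold: float = 1.0

    def validate(self, n_frames: int) -> None:
        if self.n_learn < self.n_motion_components + 2:
            raise ValueError("n_learn must be >= n_motion_components + 2")
        if self.rf_start_frame is not None:
            if self.n_learn + self.sigma_baseline_window > self.rf_start_frame:
                raise ValueError(
                    "n_learn + sigma_baseline_window must not exceed rf_start_frame"
                )
            if n_frames <= self.rf_start_frame:
                raise ValueError(
                    f"series has {n_frames} frames; needs more than "
                    f"rf_start_frame={self.rf_start_frame}"
                )
        elif n_frames < self.n_learn + self.ref_window_frames + 2:
            raise ValueError("too few frames for a stability-only run")

    @property
    def rf_start_index(self) -> int | None:
        """0-based index of the first heated frame."""
        return None if self.rf_start_frame is None else self.rf_start_frame - 1


@dataclass
class PipelineResult:
    temperature: th.TemperatureSeries
    dose: dm.ThermalDoseMap | None
    lesion: dm.LesionMeasure | None
    log: dict


def run_pipeline(series: FrameSeries, config: PipelineConfig) -> PipelineResult:
    """Run the full causal pipeline on a frame series."""
    config.validate(series.n_frames)
    n = series.n_frames
    H, W = series.frame_shape
    k = config.prfs.k
    dt = series.frame_interval_s
    rf0 = config.rf_start_index  # first heated frame, or None
    n_learn = config.n_learn
    if rf0 is not None:
        ref_end = rf0 - 1  # exclusive end of the reference window
        sig_lo = config.rf_start_frame - config.sigma_baseline_window
        sig_hi = config.rf_start_frame  # exclusive
    else:
        ref_end = n_learn + config.ref_window_frames
        sig_lo, sig_hi = n_learn, ref_end + 1

    drift_mask = (
        np.ones((H, W), dtype=bool)
        if config.drift_mask is None
        else np.asarray(config.drift_mask, dtype=bool)
    )
    t_start = time.perf_counter()
    log: dict = {"drift_rad": [], "flow_coeffs": [], "n_frames": n}

    # --- stage 1: learning ------------------------------------------------
    ref_mag = series.magnitude[0]
    unwrapper = bl.TemporalUnwrapper()
    flows = []
    learn_phases = np.empty((n_learn, H, W))
    for i in range(n_learn):
        if series.magnitude[i].shape != (H, W):
            raise ValueError("frame shape changed mid-series")
        f = reg.estimate_flow(
            series.magnitude[i], ref_mag, config.flow_smoothness,
            method=config.flow_method, frame_index=i,
        )
        flows.append(f)
        learn_phases[i] = unwrapper.update(reg.warp_phase(series.phase[i], f))
    basis = reg.build_motion_basis(flows, config.n_motion_components)
    learn_coeffs = np.stack([reg.project_motion(f, basis) for f in flows])
    model = bl.learn_phase_model(learn_phases, learn_coeffs)
    log["learn_s"] = time.perf_counter() - t_start
    log["explained_variance"] = basis.explained_variance.tolist()

    # --- stages 2-3: stream ----------------------------------------------
    dT = np.zeros((n, H, W))
    dT_raw = np.zeros((n, H, W))
    filt = bl.make_filter(config.cutoff_hz, 1.0 / dt, config.filter_order)
    ref_sum = np.zeros((H, W))
    ref_count = 0
    sigma_buf: list[np.ndarray] = []
    sigma_baseline: np.ndarray | None = None
    dose = None
    if rf0 is not None:
        dose = dm.ThermalDoseMap.zeros((H, W))

    for i in range(n_learn, n):
        if series.magnitude[i].shape != (H, W):
            raise ValueError("frame shape changed mid-series")
        f = reg.estimate_flow(
            series.magnitude[i], ref_mag, config.flow_smoothness,
            method=config.flow_method, frame_index=i,
        )
        coeffs = reg.project_motion(f, basis)
        # denoise the field by its rank-limited reconstruction
        f_proj = reg.reconstruct_motion(coeffs, basis, frame_index=i)
        phi = unwrapper.update(reg.warp_phase(series.phase[i], f_proj))
        phi = bl.correct_susceptibility(phi, coeffs, model)

        if i < ref_end:
            ref_sum += phi
            ref_count += 1
        ref_phase = ref_sum / max(ref_count, 1)

        drift = bl.estimate_drift(phi - ref_phase, drift_mask)
        raw = th.temperature_map(phi - drift, ref_phase, k)
        filt, smoothed = bl.lowpass_step(filt, raw)
        dT_raw[i] = raw
        dT[i] = smoothed
        log["drift_rad"].append(drift)
        log["flow_coeffs"].append(coeffs.tolist())

        if sig_lo <= i < sig_hi:
            sigma_buf.append(raw)
        if sigma_baseline is None and i == sig_hi - 1:
            sigma_baseline = np.std(np.stack(sigma_buf), axis=0, ddof=1)
            sigma_buf.clear()
        if dose is not None and i >= rf0:
            dm.dose_step(dose, config.t_ref_degc + smoothed, dt)

    # --- stability statistics and lesion ----------------------------------
    stats_lo, stats_hi = n_learn, (rf0 if rf0 is not None else n)
    mu = sig = excl = None
    if stats_hi - stats_lo >= 2:
        mu, sig, excl = th.temperature_stats(
            dT[stats_lo:stats_hi], config.exclusion_threshold_degc
        )
    temperature = th.TemperatureSeries(
        dT=dT, dT_raw=dT_raw, t_ref=config.t_ref_degc, valid_from=n_learn,
        mu_map=mu, sigma_map=sig, exclusion_mask=excl,
        sigma_baseline=sigma_baseline,
    )
    lesion = None
    if dose is not None:
        dose.sigma_baseline = sigma_baseline
        dm.correct_dose(dose)
        seed = np.unravel_index(np.argmax(dose.corrected), dose.corrected.shape)
        mask = dm.lethal_mask(
            dose.corrected, config.lethal_threshold, seed_point=seed
        )
        lesion = dm.lesion_dimensions(mask, series.pixel_spacing_mm)
        log["lesion_mask_pixels"] = int(mask.sum())
    log["total_s"] = time.perf_counter() - t_start
    return PipelineResult(temperature, dose, lesion, log)


# --- I/O ------------------------------------------------------------------


def _nifti(arr: np.ndarray, pixel_spacing_mm: float, dt_s: float = 1.0):
    """2D(+t) array (t, H, W) or (H, W) -> NIfTI-1 image (x, y[, t])."""
    if arr.ndim == 3:
        data = np.transpose(arr, (2, 1, 0))
        zooms = (pixel_spacing_mm, pixel_spacing_mm, dt_s)
    else:
        data = arr.T
        zooms = (pixel_spacing_mm, pixel_spacing_mm)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.eye(4))
    img.header.set_zooms(zooms)
    return img


def _from_nifti(img) -> np.ndarray:
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        return np.transpose(data, (2, 1, 0))
    return data.T


def save_series(series: FrameSeries, out_dir: str | Path) -> None:
    """Write a series as magnitude/phase 2D+t NIfTI files plus metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dt = series.frame_interval_s
    nib.save(_nifti(series.magnitude, series.pixel_spacing_mm, dt),
             out / "magnitude.nii")
    nib.save(_nifti(series.phase, series.pixel_spacing_mm, dt), out / "phase.nii")
    meta = {
        "pixel_spacing_mm": series.pixel_spacing_mm,
        "frame_interval_s": dt,
        "n_frames": series.n_frames,
    }
    (out / "series.json").write_text(json.dumps(meta, indent=2))


def load_series(in_dir: str | Path) -> FrameSeries:
    """Read back a series written by :func:`save_series`."""
    d = Path(in_dir)
    meta = json.loads((d / "series.json").read_text())
    mag = _from_nifti(nib.load(d / "magnitude.nii"))
    phase = _from_nifti(nib.load(d / "phase.nii"))
    t = np.arange(meta["n_frames"]) * meta["frame_interval_s"]
    return FrameSeries(mag, phase, t, meta["pixel_spacing_mm"])


def write_report(
    result: PipelineResult,
    out_dir: str | Path,
    pixel_spacing_mm: float,
    frame_interval_s: float = 1.0,
) -> Path:
    """Write maps (NIfTI), lesion/ROI tables (CSV) and a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    T = result.temperature
    nib.save(_nifti(T.dT[-1], pixel_spacing_mm), out / "dT_final.nii")
    if T.mu_map is not None:
        nib.save(_nifti(T.mu_map, pixel_spacing_mm), out / "mu_T.nii")
        nib.save(_nifti(T.sigma_map, pixel_spacing_mm), out / "sigma_T.nii")
    if T.sigma_baseline is not None:
        nib.save(_nifti(T.sigma_baseline, pixel_spacing_mm),
                 out / "sigma_baseline.nii")
    if result.dose is not None:
        nib.save(_nifti(result.dose.cem43, pixel_spacing_mm), out / "cem43.nii")
        if result.dose.corrected is not None:
            nib.save(_nifti(result.dose.corrected, pixel_spacing_mm),
                     out / "cem43_corrected.nii")

    lesion = result.lesion
    lines = ["largest_mm,smallest_mm,area_mm2,centroid_row,centroid_col"]
    if lesion is None:
        lines.append("no lesion,,,,")
    else:
        lines.append(
            f"{lesion.largest_mm:.3f},{lesion.smallest_mm:.3f},"
            f"{lesion.area_mm2:.3f},{lesion.centroid[0]:.2f},{lesion.centroid[1]:.2f}"
        )
    (out / "lesion.csv").write_text("\n".join(lines) + "\n")

    summary = {
        "t_ref_degc": T.t_ref,
        "n_frames": T.n_frames,
        "lesion": None
        if lesion is None
        else {
            "largest_mm": lesion.largest_mm,
            "smallest_mm": lesion.smallest_mm,
            "area_mm2": lesion.area_mm2,
        },
        "max_dT_degc": float(T.dT.max()),
        "log": {k: v for k, v in result.log.items() if k != "flow_coeffs"},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out
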