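"""Thermometry precision on an unheated phantom (volunteer-style run).

Runs the full correction chain (registration, susceptibility model,
drift compensation, PRFS conversion, temporal filter) on a heating-free
series with breathing, susceptibility coupling and drift all on, then
summarises the per-pixel temporal mean and standard deviation of
temperature over the myocardial ROI — the standard stability figures of
merit for cardiac MR thermometry.
"""

from scipy.ndimage import binary_erosion

from cardiotherm import (
    PhantomConfig, PipelineConfig, PRFSParams, generate_series,
    roi_summary, run_pipeline, temperature_stats,
)

k = PRFSParams().k
config = PhantomConfig(n_frames=180, heat_peak_degc=0.0, snr=80.0,
                       drift_rate_rad_s=5.0 / (k * 150.0), seed=11)
series, truth = generate_series(config)

result = run_pipeline(
    series, PipelineConfig(rf_start_frame=None, drift_mask=truth.body_mask)
)
roi = binary_erosion(truth.body_mask, iterations=6)
mu, sigma, excluded = temperature_stats(result.temperature.dT[30:])
summary = roi_summary(mu, sigma, excluded, roi)

print(f"ROI mean sigma_T = {summary.mean_sigma:.2f} degC "
      f"(temporal precision; pixels with sigma_T > 7 degC are excluded)")
print(f"ROI mean mu_T    = {summary.mean_mu:+.3f} degC "
      f"(residual bias; the ~5 degC drift is removed by the median estimate)")
print(f"excluded pixels  = {100 * summary.fraction_excluded:.1f}% of the ROI")
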