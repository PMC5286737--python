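"""Estimate breathing motion with optical flow and build the PCA basis.

Respiratory motion in-plane is essentially one-dimensional, so the first
principal component of the per-frame flow fields captures nearly all the
variance; its coefficient traces the breathing waveform and later drives
the susceptibility-phase correction.
"""

import numpy as np

from cardiotherm import PhantomConfig, generate_series
from cardiotherm.registration import (
    build_motion_basis, estimate_flow, project_motion, warp,
)

config = PhantomConfig(n_frames=30, heat_peak_degc=0.0, heat_onset_frame=0,
                       heat_duration_frames=0, snr=150.0, seed=1)
series, truth = generate_series(config)

flows = [estimate_flow(series.magnitude[i], series.magnitude[0])
         for i in range(series.n_frames)]
basis = build_motion_basis(flows, n_components=2)
coeffs = np.stack([project_motion(f, basis) for f in flows])

mov = series.magnitude[2]
mse_before = np.mean((mov - series.magnitude[0]) ** 2)
mse_after = np.mean((warp(mov, flows[2]) - series.magnitude[0]) ** 2)

print(f"explained variance of motion components: "
      f"{basis.explained_variance.round(4)}")
print("  (one dominant mode = the 1D breathing manifold)")
print(f"registration cuts frame-2 intensity MSE by "
      f"{100 * (1 - mse_after / mse_before):.0f}%")
print(f"first-component coefficient tracks breathing: "
      f"correlation with true displacement = "
      f"{abs(np.corrcoef(coeffs[:, 0], truth.true_motion_px[:30, 0])[0, 1]):.3f}")
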