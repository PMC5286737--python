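# Methods

This note records the models, defaults and numerical choices behind
`cardiotherm`, and what the synthetic phantom does and does not
establish about real scanner data.

## PRFS temperature model

Temperature change is read from phase differences,
ΔT = (φ_t − φ_ref)·k with k = (2π·(γ/2π)·α·B₀·TE)⁻¹. Defaults:
γ/2π = 42.58 MHz/T, α = −0.0094 ppm/°C, B₀ = 1.5 T, TE = 18 ms, giving
k ≈ −14.73 °C/rad. The sign is kept: heating lowers phase. The phantom
writes its heating phase through the same signed constant, so recovery
is sign-consistent by construction; displayed maps use ΔT directly.
Absolute temperature is T = T_ref + ΔT with T_ref the body (rectal)
reference, default 37.0 °C.

Phase differences are unwrapped *temporally*, per pixel, assuming the
inter-frame change stays below π. This is comfortably valid — even the
fastest heating here moves the phase by well under a radian per 1 s
frame (75 °C / 14.73 °C·rad⁻¹ ≈ 5 rad spread over ~40 frames). Spatial
unwrapping is not attempted; with real data, standing wraps at organ
interfaces degrade σ_T locally and those pixels are handled by the
exclusion rule rather than repaired.

## Registration and the motion model

In-plane motion is estimated on magnitude images as dense variational
optical flow (scikit-image TV-L1 by default; iterative Lucas–Kanade as
a faster option). The `smoothness` argument scales the regularisation
relative to the data term. The flow fields of the 30 learning frames
are decomposed by PCA; respiratory motion is essentially 1-D, so the
first component dominates (≥95% variance on phantom data). During the
intervention each fresh field is projected onto the 2-component basis
— this denoises the field and yields the compact motion coefficients
that drive the susceptibility model. The registration reference is the
first frame of the series. Displacement fields map reference
coordinates to sampling positions in the moving frame ((row, col),
0-based, pixel-centred); warping is bilinear with nearest-edge
extrapolation and an out-of-bounds validity mask, and phase is warped
through (cos, sin) to avoid wrap artifacts.

## Susceptibility and drift correction

Breathing modulates the local field, adding a motion-correlated phase
that aliases into temperature (several °C if uncorrected). Over the
learning frames each pixel's registered, unwrapped phase is fit by OLS
against the motion coefficients (design matrix [1, c₁, c₂]); during the
intervention the motion-dependent part is subtracted. A rank-deficient
design (no motion variance) falls back to intercept-only with a
warning. The correction is linear and deliberately not idempotent; the
pipeline applies it exactly once per frame.

Scanner field drift is modelled as spatially uniform per frame and
estimated as the median of the phase difference (current − reference)
over a mask of pixels known to stay unheated; the caller supplies the
mask (for phantom runs: tissue farther than 4 heating-widths from the
focus). The median is robust to the heated tail when the mask is
imperfect. A first-order spatial drift model was considered and left
out: on 2–3 min series the uniform term removes the bulk of the effect
(residual |μ_T| < 0.3 °C on drift-only phantoms at the ~5 °C/150 s
drift level).

The reference phase is the causal running mean of the corrected phase
over the window between learning and RF start (frames 31–49 under the
defaults); averaging ~19 frames reduces reference noise by the familiar
√(1+1/N) factor. Causality is strict throughout: outputs at frame t
depend only on frames ≤ t, verified by a truncation test.

## Temporal filter

Temperature maps are filtered pixelwise by a causal order-2 Butterworth
low-pass, cutoff 0.14 Hz at the ~1 Hz frame rate (order chosen for a
real-time-safe, low-lag response; only the cutoff is prescribed by the
method). The streaming state is a direct-form-II-transposed register
per pixel, warm-started on the first sample so a constant input is
reproduced exactly (unit DC gain). The discrete filter rings by ~6% on
a step and lags a rising ramp by ~1 s; consequently the reported peak
ΔT of a still-rising hotspot sits 1–3% below truth. σ_T for the dose
correction is computed on the *unfiltered* ΔT over the 20 pre-RF
frames — the conservative (larger σ, smaller dose) choice.

## Thermal dose and lesion extraction

Dose is accumulated causally with the rectangle rule: the current
frame's temperature is held over [t, t+Δt], R = 2^(T−43) at or above
43 °C and 4^(T−43) below, Δt = frame interval. 240 CEM43 is the lethal
threshold (normalised 1). The uncertainty correction multiplies by
exp(−0.5(ln2·σ_T)²) ∈ (0,1]; at σ_T = 1.5 °C the dose retains 58%, at
the 7 °C exclusion level it is suppressed (~10⁻⁵). Correction commutes
with thresholding only for spatially uniform σ_T.

**Integration-accuracy envelope.** Against a dense (100-substep,
linear-in-time) integration of the same curve, the frame-resolution
accumulator agrees exactly at one substep by construction, and the
worst-pixel relative dose error grows with the per-frame temperature
step because the integrand is exponential in T: ≈0.6% at 1 °C/frame,
≈2% at 2 °C/frame, ≈4% at 3 °C/frame (1 s frames). The 2% figure
quoted in the tests therefore applies to heating rates up to
~1.5–2 °C/s; clinically relevant rises (tens of °C over tens of
seconds) sit inside this envelope, and even at 3 °C/s the lesion
*boundary* is unaffected because the dose crosses threshold over many
orders of magnitude within a pixel.

The lesion is the 8-connected supra-threshold component containing (or
nearest to) the dose maximum; other components are logged and
discarded. An empty mask is a valid "no lesion" outcome, reported as
such. Dimensions are principal-axis extents of the pixel-centre cloud
(max − min projection + one pixel, in mm) — for compact blobs these
coincide with ruler-style largest/smallest measurements and are exactly
reproducible, unlike Feret diameters on coarse masks.

## Synthetic phantom

The phantom emulates one imaging slice of a monitored ablation at one
frame per cardiac cycle: a soft-edged disc anatomy with deterministic
low-frequency texture (so optical flow is well posed), plateau
magnitude 1; rigid sinusoidal in-plane translation (default 24
breaths/min, 5 mm amplitude — the in-plane *residual* after slice
tracking, for which the reported total respiratory excursion is an
upper bound); a susceptibility phase linear in displacement with a
planar gain map (0–0.1 rad/mm across the FOV); uniform drift (default
equivalent to +5 °C over 150 s); a Gaussian heating focus (default
σ = 3 mm) with exponential rise/decay envelope, RF on at the 50th
frame; and complex Gaussian noise (Rician magnitude), phase noise
≈ 1/SNR at unit magnitude, default SNR 80. Grid 96×96 at the 0.8 mm
reconstructed pixel; 200 frames by default (the problem sizes used in
the tests — 110–220 frames, 48–96 px grids — are chosen to keep a desk
run in minutes while leaving every effect well resolved).

Tissue-attached phase terms (anatomy, heating, susceptibility) are
composed in the tissue frame and warped together with the anatomy, so
the ground truth lives in the registered frame the pipeline
reconstructs, and the learned linear susceptibility model is exact by
construction up to interpolation. The drift, a scanner-wide effect, is
added after warping. The seed drives only the noise; ground-truth
means are seed-independent, and identical config+seed is bit-identical.

What the phantom does *not* emulate — and what passing tests therefore
do not show about real data: cardiac contraction and through-plane
motion, spatial phase wraps at organ interfaces, blood flow and
saturation effects, catheter susceptibility artifacts, non-rigid
deformation, and physical heat conduction (the heating field is
analytic and separable, not a bioheat solution; this is what makes a
closed-form oracle possible). In-vivo precision figures can only be
bracketed, not reproduced: the tests check σ_T ≤ 2 °C and |μ_T| ≤
0.7 °C on the perturbed unheated phantom, bands containing the
reported volunteer values.

`true_dose` integrates the CEM43 integrand densely on the *true*
temperature (linear interpolation between frames, left-endpoint
substeps) and is the independent oracle for the streaming accumulator
and for lesion recovery: across heating peaks of 20–75 °C the pipeline
lesion agrees with the oracle lesion within one pixel (0.8 mm).

## Lesion concordance record

The packaged CSV holds the 12 in-vivo ablations (3 animals): power,
duration, energy (= power × duration exactly, validated on load),
maximal temperature, and paired TD-map / T1-weighted lesion dimensions.
Dimension pairs are matched positionally as recorded (a sort-descending
option exists); regression is TD on T1-w. From these 0.5 mm-rounded
dimensions the analysis gives r = 0.915, slope 1.06, bias
0.46 ± 1.08 mm — close to, but deliberately not identical with, the
published figure-based values (r = 0.87, slope 1.01, bias
0.63 ± 1.3 mm), which were measured on finer-resolution images. The
tests therefore assert r at least as strong as 0.87 and the
bias/slope neighbourhoods, not exact equality.

## Known limitations

* Rigid-translation motion only in the phantom; the registration stage
  itself is dense and would handle mild non-rigidity, but this is
  untested here.
* The drift mask must be supplied by the caller; there is no automatic
  detection of the heated region.
* Sub-pixel interpolation during registration smooths phase noise by
  up to ~10%, so pipeline σ_T sits slightly below the pure propagation
  prediction; the prediction is verified on unregistered series.
* Multi-slice series are processed independently per slice (no
  inter-slice coupling), matching the acquisition's independent-slice
  geometry.
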