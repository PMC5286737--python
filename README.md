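# cardiotherm

Real-time cardiac MR thermometry and thermal dosimetry for monitoring
radiofrequency (RF) catheter ablation of the myocardium.

RF ablation treats cardiac arrhythmia by heating small regions of heart
muscle, but the operator normally cannot see the lesion forming.
Proton-resonance-frequency-shift (PRFS) MR thermometry makes the
temperature visible: the water proton resonance shifts by about
−0.01 ppm/°C, so the phase of a gradient-echo image tracks temperature.
`cardiotherm` implements the full processing chain that turns a dynamic
2D+time magnitude/phase series into temperature maps, accumulated
thermal dose and a predicted lesion size, together with a synthetic
phantom that makes every stage testable without a scanner. It is aimed
at researchers developing or validating interventional MR thermometry
pipelines.

## Method

Temperature change per pixel is

```
ΔT = (φ_t − φ_ref) · k,    k = (2π · γ/2π · α · B₀ · TE)⁻¹
```

with γ/2π = 42.58 MHz/T, α = −0.0094 ppm/°C, B₀ = 1.5 T and
TE = 18 ms by default (|k| ≈ 14.73 °C/rad). On the beating, breathing
heart the raw phase is unusable, so each frame passes through a causal
correction chain:

1. **Registration** — dense optical flow on the magnitude image against
   a fixed reference; phase is resampled through its complex
   representation.
2. **Susceptibility correction** — during 30 learning frames, a PCA
   basis of the motion fields is built and each pixel's phase is
   regressed on the motion coefficients; afterwards the motion-predicted
   phase is subtracted from every incoming frame.
3. **Drift correction** — the median phase offset over pixels known to
   stay unheated removes the slow scanner field drift (worth several °C
   over minutes if ignored).
4. **Temporal filtering** — a causal order-2 Butterworth low-pass
   (cutoff 0.14 Hz) exploits the slow evolution of tissue temperature
   relative to the ~1 s frame interval.

Thermal dose is accumulated online as cumulative equivalent minutes at
43 °C (CEM43),

```
TD = Σ R^(T−43) Δt,   R = 2 above 43 °C (4 below);  240 CEM43 = lethal
```

discounted for thermometry noise by
`TD_corrected = TD · exp(−0.5 (ln2 · σ_T)²)` with σ_T measured over 20
pre-ablation frames. The lesion is the connected supra-threshold
component; its size is reported as principal-axis extents in mm. The
package also ships the record of 12 in-vivo ventricular ablations and
the agreement statistics (Pearson, regression, Bland–Altman) between
dose-map and T1-weighted lesion dimensions.

## Worked example

`examples/04_ablation_monitoring.py` simulates a 60 °C ablation focus
(RF on at the 50th frame for 40 s) under breathing motion,
susceptibility coupling, drift and noise, runs the pipeline, and checks
the lesion against a dense integration of the known true temperature:

```
peak measured dT: 56.4 degC (true 57.9 degC)
peak dose: 9.24e+11 x lethal (the CEM43 law is exponential in temperature)
lesion from pipeline TD map: 9.6 x 9.6 mm
lesion from true-temperature dose: 9.6 x 9.6 mm  (agreement within one 0.8 mm pixel)
```

The measured peak sits slightly below truth because the causal temporal
filter lags a still-rising temperature; the exponential dose law makes
the central dose astronomically supra-lethal while the lesion *boundary*
— the quantity that matters — is recovered to within one pixel.
`examples/06_lesion_concordance.py` reproduces the in-vivo agreement
analysis:

```
TD vs T1-w dimensions (N = 24):
  Pearson r = 0.92  (strong linear agreement between the two measurements)
  regression TD = 1.06 x T1w + 0.06 mm
  Bland-Altman bias = 0.46 +/- 1.08 mm, 95% limits [-1.66, 2.58] mm
```

The other examples cover phantom generation, motion-basis construction,
volunteer-style stability analysis and the analytic dose law. A thin
CLI mirrors the library (`cardiotherm simulate|run|dose|lesion|concordance|report`).

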