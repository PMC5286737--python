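"""The CEM43 dose law and the uncertainty correction, on analytic cases.

One minute at T degC counts as 2^(T-43) equivalent minutes at 43 degC
above threshold (4^(T-43) below); 240 equivalent minutes is the lethal
exposure.  Noisy thermometry inflates apparent dose, so the accumulated
map is discounted by exp(-0.5 (ln2 sigma_T)^2).
"""

import numpy as np

from cardiotherm import ThermalDoseMap, dose_correction_factor, dose_step

for t_degc, minutes in [(43.0, 240.0), (44.0, 120.0), (42.0, 240.0)]:
    dose = ThermalDoseMap.zeros((1, 1))
    for _ in range(int(minutes)):
        dose_step(dose, np.full((1, 1), t_degc), 60.0)
    print(f"{t_degc:.0f} degC for {minutes:5.0f} min -> "
          f"{dose.cem43[0, 0]:6.1f} CEM43 "
          f"({dose.normalized[0, 0]:.2f} x the lethal threshold)")

for sigma in (0.0, 0.5, 1.5, 7.0):
    print(f"sigma_T = {sigma:3.1f} degC -> dose retained "
          f"{100 * dose_correction_factor(sigma):7.3f}%")
print("(at sigma_T = 7 degC, the exclusion level, dose is fully suppressed)")
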