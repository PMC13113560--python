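"""Temperature-scaled confidences and power-law modality weights.

Shows how the calibrator maps two modality logit vectors to a single pair
of fusion weights, and how the temperature T and exponent alpha reshape
that mapping.
"""

import numpy as np

from cabif import CalibratorParams, calibrate, confidence_weights

zv = np.log([6.0, 3.0, 1.0])  # confident visual prediction
za = np.array([0.2, 0.1, 0.0])  # nearly uninformative audio

w = calibrate(zv, za, CalibratorParams())
print(f"identity calibrator (Tv=Ta=alpha=1): cv={float(w.cv):.3f} "
      f"ca={float(w.ca):.3f} -> wv={float(w.wv):.3f} wa={float(w.wa):.3f}")

hot = CalibratorParams(tv=np.array(5.0))
w_hot = calibrate(zv, za, hot)
print(f"Tv=5 flattens the visual distribution: cv={float(w_hot.cv):.3f} "
      f"-> wv={float(w_hot.wv):.3f} (the visual lead shrinks)")

for alpha in (0.1, 1.0, 4.0):
    wv = float(confidence_weights(0.7, 0.4, alpha).wv)
    print(f"alpha={alpha:>4}: cv=0.7, ca=0.4 -> wv={wv:.3f}")
print("larger alpha hands the confident modality a larger share; "
      "alpha < 1 evens the split; wv + wa = 1 always")
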