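"""Calibrate raw scores against active / inactive / ambiguous labels.

Raw factorization scores are not probabilities.  Binning labelled scores
(width 0.05, outliers above 1.10 dropped), the ambiguous-class histogram is
modelled as a w1/w2 mixture of the active and inactive histograms; w2/w1
then inflates the under-represented inactive counts before the per-bin
adjusted score B = pos / (pos + floor(ratio * neg)) is computed.
"""

import numpy as np

from dtocf import calibrate_score, fit_calibration

rng = np.random.default_rng(0)
scored = []
# actives concentrate near 1, inactives near 0 — the separation the raw
# scores show when the model fits well; ambiguous pairs are a mixture
scored += [(float(s), "active") for s in np.clip(rng.normal(0.85, 0.2, 2000), 0, 1.3)]
scored += [(float(s), "inactive") for s in np.clip(rng.normal(0.15, 0.15, 400), 0, 1.3)]
mix = np.where(rng.random(600) < 0.3,
               rng.normal(0.85, 0.2, 600), rng.normal(0.15, 0.15, 600))
scored += [(float(s), "ambiguous") for s in np.clip(mix, 0, 1.3)]

calibration = fit_calibration(scored)
print(f"fitted mixture weight w1 = {calibration.w1:.3f} "
      f"(fraction of ambiguous pairs behaving like actives)")
print(f"inflation ratio w2/w1 = {calibration.inflation_ratio:.2f} "
      f"(each inactive count is multiplied by this, rounded down)\n")
print("raw score -> calibrated score:")
for raw in (0.1, 0.4, 0.7, 0.95, 1.2):
    print(f"  {raw:4.2f} -> {calibrate_score(raw, calibration):.3f}")
print("\nCalibrated values estimate the probability that a prediction at that "
      "raw score is a true interaction, after correcting the class imbalance; "
      "1.2 is above the outlier limit and clamps to the top bin.")
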