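"""Why the fitted R² is the wrong yardstick for deconvolution accuracy.

A predictor that over-estimates every proportion by a constant 0.2 has a
perfect linear relationship with the truth, so the regression (fitted,
adjusted) R² is exactly 1 — yet every prediction is off by 0.2.  The RMSE
and the diagonal R² (fit to the identity line true = pred) both expose the
bias.  Use RMSE or diagonal R² to judge deconvolution; keep fitted R² only
for checking linearity.
"""

import numpy as np

import simplesig as ss

true = np.array([0.05, 0.15, 0.3, 0.5, 0.7])
for label, pred in [("perfect", true), ("pred = true + 0.2", true + 0.2)]:
    m = ss.deconvolution_metrics(true, pred)
    print(f"{label:18}  rmse={m.rmse:.3f}  r2_fit={m.r2_fit:.3f}  "
          f"r2_diagonal={m.r2_diagonal:.3f}  "
          f"(slope={m.fit_slope:.2f}, intercept={m.fit_intercept:.2f})")
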