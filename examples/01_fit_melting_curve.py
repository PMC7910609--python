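"""Fit a single protein melting curve.

Builds a noisy relative-solubility curve from the three-parameter sigmoid
(melting temperature Tm, slope b, high-temperature plateau Pl), fits it by
bounded nonlinear least squares and prints the recovered parameters.
"""

import numpy as np

from meltscreen import TemperatureGrid, fit_melting_curve, melt_model

grid = TemperatureGrid()  # 37-67 °C, 10 points
temps = np.array(list(grid))

true_tm, true_b, true_pl = 52.0, 0.035, 0.08
rng = np.random.default_rng(0)
fractions = melt_model(temps, true_tm, true_b, true_pl) + rng.normal(0, 0.02, 10)

fit = fit_melting_curve(temps, fractions)

print(f"true:   Tm={true_tm:.2f} °C  b={true_b:.4f}  Pl={true_pl:.3f}")
print(f"fitted: Tm={fit.tm:.2f} °C  b={fit.slope:.4f}  Pl={fit.plateau:.3f}  "
      f"R²={fit.r2:.4f}")
print()
print("Tm is the temperature of half-transition between the folded baseline")
print("(fraction 1 at 37 °C) and the residual plateau; R² > 0.7 is the")
print("fit-quality gate a curve must pass to enter the screen.")
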