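"""Calibrating the expression-to-flux constant C.

The toy growth variant secretes C as 'biomass' with yield 1, giving the
closed-form growth rate min(E_g1 + E_g2, E_g3) * C = 5C. Growth rates are
planted with C* = 0.8; the sweep should land within one grid step of it.
"""

import numpy as np
import pandas as pd

import mri

growth_model = mri.convert_model(mri.toy1_model(growth=True))
wt, _ = mri.toy1_profiles()
medium = mri.toy1_medium()

C_star = 0.8
phenotypes = mri.PhenotypeTable(
    pd.DataFrame({"growth_rate": [5.0 * C_star]}, index=["WT"])
)

for C in (0.1, 0.8, 2.0):
    mu = mri.predict_growth_rate(growth_model, wt, medium, C)
    print(f"C = {C:4.1f}: predicted growth = {mu:.3f} 1/h (closed form {5*C:.3f})")

grid = np.geomspace(0.05, 12.8, 17)
curve = mri.calibrate_C(growth_model, [wt], phenotypes, medium, grid)
print(f"planted C* = {C_star}, recovered C = {curve.optimum:.3f}, "
      f"min mean relative error = {curve.errors.min():.4f}")
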