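"""Forward model and look-up-table inversion of optical properties.

Evaluates spatially modulated diffuse reflectance for a tissue-like
medium, builds the (mu_a, mu_s') -> (R_DC, R_AC) table, and inverts a
synthetic reflectance pair back to optical properties.
"""

import numpy as np

from ssopkit import (
    OpticalProperties,
    build_lut,
    diffuse_reflectance,
    invert_optical_properties,
)

op = OpticalProperties(mu_a=0.01, mu_s_prime=1.0, n=1.4)
rd0 = diffuse_reflectance(op, 0.0)
rd2 = diffuse_reflectance(op, 0.2)
print(f"R_d(fx=0.0) = {rd0:.4f}   R_d(fx=0.2) = {rd2:.4f}")
print("-> the modulated reflectance is always dimmer: high spatial "
      "frequencies probe shallow depths and decay faster.\n")

lut = build_lut()  # 201x201 grid, fx pair (0, 0.2) cycles/mm, n=1.4
truth = OpticalProperties(mu_a=0.023, mu_s_prime=1.7)
pair = (diffuse_reflectance(truth, 0.0), diffuse_reflectance(truth, 0.2))
ops = invert_optical_properties(np.array([pair[0]]), np.array([pair[1]]), lut)
print(f"truth:     mu_a = {truth.mu_a:.4f}  mu_s' = {truth.mu_s_prime:.3f} mm^-1")
print(f"recovered: mu_a = {ops.mu_a[0]:.4f}  mu_s' = {ops.mu_s_prime[0]:.3f} mm^-1")
print("-> LUT inversion (nearest node + local refinement) recovers the "
      "pair to a fraction of a grid cell.")
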