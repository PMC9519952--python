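"""Young's modulus from the linear portion of a tensile test.

Builds a stress-strain curve with a compliant quadratic toe region
followed by a linear segment, and lets the automatic window search find
the most linear contiguous region.
"""

import numpy as np

from tissueqc.mechanics import TensileRecord, youngs_modulus_tensile

rng = np.random.default_rng(8)
toe = np.linspace(0, 0.02, 60)
lin = np.linspace(0.02, 0.12, 240)
strain = np.concatenate([toe, lin])
stress = np.concatenate([
    2000.0 * toe**2 / (2 * 0.02),                    # toe: stiffening
    2000.0 * 0.02 / 2 + 2000.0 * (lin - 0.02),       # linear: slope 2000 kPa
])
stress = stress + rng.normal(0, 0.5, stress.size)     # load-cell noise

rec = TensileRecord(strain, stress, gauge_length=6.0)
E, info = youngs_modulus_tensile(rec)
lo, hi = info["window_strain"]
print(f"Young's modulus: {E:.0f} kPa (true linear slope 2000 kPa)")
print(f"fit window: strain {lo:.3f}..{hi:.3f}, {info['n_points']} points, "
      f"R^2 = {info['r2']:.4f}")
# the auto window excludes the toe region, so the slope reflects the
# linear segment only
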