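"""FitzHugh-Nagumo as two 1-D modules: the degenerate case where the
pseudo-nullclines coincide with the textbook nullclines.

Builds the split system, traces both curves, refines their intersection and
compares it with a brute-force root sweep of the full 2-D system.
"""

import numpy as np

from pseudonullclines import (NullclineGeometry, SweepConfig, intersections_of,
                              sweep_system_roots)
from pseudonullclines.models import get_model
from pseudonullclines.models.toys import fhn_v_nullcline_w

fhn = get_model("fhn_toy")
geo = NullclineGeometry(range1=(-1.5, 2.5), range2=(-2.5, 2.5))

(fixed_point,) = intersections_of(fhn, geo)
v, w = fixed_point.state
print(f"pseudo-nullcline intersection: v = {v:.6f}, w = {w:.6f}")
print(f"  classification: {fixed_point.classification}, "
      f"stability: {fixed_point.stability}")
print(f"  on the cubic nullcline? residual = "
      f"{abs(fhn_v_nullcline_w(v, fhn.params) - w):.2e}")

(brute,) = sweep_system_roots(fhn, SweepConfig(n_starts=200))
print(f"brute-force root of the full system:  v = {brute[0]:.6f}, w = {brute[1]:.6f}")
print(f"  max coordinate difference: {np.max(np.abs(fixed_point.state - brute)):.2e}")
# An unstable focus at a transversal crossing is the classic sub-threshold
# FHN configuration: the system oscillates around it.
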