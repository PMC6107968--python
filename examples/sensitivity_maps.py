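"""Sensitivity maps: which parameter combinations explain measured tenacity.

Sweeps the capillary tenacity over meniscus curvature radii and the
van der Waals tenacity over (Hamaker constant, gap width), masks the
regions compatible with the measured 0.17-1.29 mN/mm^2 band, and prints
the headline inversions those maps imply.
"""

import numpy as np

from toepad import (
    critical_gap_vdw,
    feasible_region,
    hamaker_lower_bound,
    predict_meniscus_curvature,
    sweep_capillary,
    sweep_vdw,
)
from toepad.constants import GAMMA_MUCUS, K_B, T_LAB
from toepad.sensitivity import Axis, SweepGrid

BAND = (0.17, 1.29)  # measured tenacity range [mN/mm^2]

# capillary: R_mer 1 um - 1 mm vs R_azi 0.1 - 10 mm
cap = sweep_capillary(
    SweepGrid(Axis("r_mer_m", 1e-6, 1e-3, 200), Axis("r_azi_m", 1e-4, 1e-2, 60)),
    GAMMA_MUCUS,
)
cap_region = feasible_region(cap, *BAND)
r_mer = cap.grid.x.values()
feasible = r_mer[cap_region.mask[-1]]  # at the widest meniscus footprint
print(f"capillary-compatible R_mer: {feasible.min() * 1e6:.0f}-{feasible.max() * 1e6:.0f} um")
print(f"predicted meniscus radius : "
      f"{predict_meniscus_curvature(BAND[0] * 1e3, BAND[1] * 1e3, GAMMA_MUCUS) * 1e6:.0f} um")

# van der Waals: A_H 1e-21 - 1e-19 J vs gap 0.1 - 100 nm, 10% contact
vdw = sweep_vdw(
    SweepGrid(Axis("hamaker_J", 1e-21, 1e-19, 80), Axis("gap_m", 1e-10, 1e-7, 80)),
    effective_fraction=0.1,
)
vdw_region = feasible_region(vdw, *BAND)
print(f"vdW-feasible grid cells   : {int(np.sum(vdw_region.mask))} of {vdw_region.mask.size}")

a_min = hamaker_lower_bound(T_LAB, K_B)
print(f"thermal Hamaker bound     : {a_min * 1e21:.1f} x 10^-21 J")
print(f"gap for 1 mN/mm^2 at bound: {critical_gap_vdw(1e3, a_min, 0.1) * 1e9:.1f} nm")
print(f"gap, 0.5 mN/mm^2 at 10x A : {critical_gap_vdw(0.5e3, 10 * a_min, 0.1) * 1e9:.1f} nm")

# A meniscus ~150 um in radius, or molecular-scale gaps of a few nm, are
# each sufficient to produce the tenacities measured on real pads.
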