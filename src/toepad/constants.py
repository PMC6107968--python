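"""Default physical constants for the mucus/water system (SI units)."""

import math

#: Surface tension of the pad mucus, approximated by water near 25 °C [N/m].
GAMMA_MUCUS = 71.97e-3

#: Dynamic viscosity of toe-pad mucus measured by laser-tweezer
#: micro-rheometry [Pa·s].
MU_MUCUS = 1.43e-3

#: Static contact angle of mucus on common substrates; mucus wets almost
#: perfectly, so the default is 0 [rad].
PHI_MUCUS = 0.0

#: Standard gravity [m/s²].
G_STANDARD = 9.81

#: Density of water [kg/m³].
RHO_WATER = 1000.0

#: Boltzmann constant, rounded value conventionally used in Hamaker-bound
#: estimates [J/K]. The CODATA value is available as ``K_B_EXACT``.
K_B = 1.4e-23

#: Exact (CODATA 2019) Boltzmann constant [J/K].
K_B_EXACT = 1.380649e-23

#: Laboratory temperature 26 °C in kelvin.
T_LAB = 299.15

#: Conversion: degrees to radians.
DEG = math.pi / 180.0
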