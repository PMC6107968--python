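"""The candidate force laws of wet pad adhesion, evaluated at pad scale.

Evaluates each analytical model at parameter values typical of a toe pad
(1.8 mm contact radius, mucus film a few micrometres thick) and prints the
force plus its per-area tenacity so the mechanisms can be compared with
the ~0.2-1.5 mN mm^-2 measured for real pads.
"""

import math

from toepad import (
    LoadState,
    Meniscus,
    SqueezeFilm,
    VdwContact,
    capillary_length,
    capillary_plate,
    classify_drainage,
    classify_lubrication,
    coulomb_friction,
    drainage_crossover,
    shear_film_friction,
    squeeze_film_plate,
    stribeck_number,
    vdw_adhesion,
)
from toepad.constants import GAMMA_MUCUS, MU_MUCUS
from toepad.geometry import default_geometry
from toepad.mechanics import adhesive_magnitude

R_PAD = 1.8e-3  # pad contact radius [m]
AREA = math.pi * R_PAD**2


def show(name, force):
    print(f"{name:28s} {force * 1e3:10.4g} mN   {force / AREA * 1e-3:8.3g} mN/mm^2")


# capillary bridge spanning the pad rim, meniscus radius 150 um
men = Meniscus(surface_tension=GAMMA_MUCUS, r_azi=R_PAD, r_mer=150e-6)
show("capillary (R_mer=150um)", capillary_plate(men))
print(f"{'capillary length':28s} {capillary_length(GAMMA_MUCUS, 1000, 9.81) * 1e3:10.3g} mm")

# squeeze film while the pad lifts off at 10 um/s across a 5 um gap
film = SqueezeFilm(viscosity=MU_MUCUS, gap=5e-6, gap_rate=10e-6, plate_radius=R_PAD)
show("squeeze film (lift-off)", adhesive_magnitude(squeeze_film_plate(film)))

# free shear flow at 500 um/s sliding across the same gap
shear = SqueezeFilm(viscosity=MU_MUCUS, gap=5e-6, area=AREA, sliding_speed=500e-6)
show("shear film (sliding)", shear_film_friction(shear))

# van der Waals across a 2.5 nm gap, 10% of the area in close contact
vdw = VdwContact(hamaker=2.9e-21, gap=2.5e-9, area=AREA, effective_fraction=0.1)
show("vdW (2.5nm, f_eff=0.1)", vdw_adhesion(vdw))

# dry friction of the pad's own adhesion acting as load
load = LoadState(adhesion=vdw_adhesion(vdw), friction_coefficient=0.77)
show("Coulomb friction", coulomb_friction(load))

# lubrication and drainage regimes
st = stribeck_number(MU_MUCUS, 500e-6, 1000.0)
print(f"{'Stribeck number':28s} {st:10.3g} m    regime: {classify_lubrication(st).value}")
cell = default_geometry().cell
d0 = drainage_crossover(cell)
print(f"{'drainage crossover':28s} {d0 * 1e6:10.3g} um   5 um gap: "
      f"{classify_drainage(5e-6, d0).value} field")

# Capillary and vdW forces reach the measured tenacity range; free shear
# flow at micrometre gaps is far too weak to explain measured friction.
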