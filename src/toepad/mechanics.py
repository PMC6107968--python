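"""Force laws and regime classifiers for wet pad–substrate contact.

Implements the classical analytical models proposed for tree-frog
attachment:

* capillary bridge adhesion between two flat plates and between a rigid
  sphere and a plate, including the small-filling-angle limit ``4πRγ``;
* the capillary length of a liquid, bounding the height of a concave
  meniscus on a hydrophilic substrate;
* Stefan (squeeze-film) hydrodynamic adhesion for plate–plate and
  sphere–plate contacts, and free-shear hydrodynamic friction;
* macroscopic van der Waals adhesion between flat plates, with the thermal
  (zero-frequency) lower bound on the Hamaker constant;
* Coulomb (dry) friction;
* the Stribeck number and its mapping onto lubrication regimes;
* the drainage crossover gap width of a channelled surface and the
  far/intermediate/near-field drainage classifier;
* the effective (plane-strain) elastic modulus.

Sign convention: attractive normal forces are reported positive by the
``*_adhesion`` helpers; the squeeze-film laws return the signed force,
which always opposes the gap motion (negative while the gap opens), with
:func:`adhesive_magnitude` as a convenience accessor.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from toepad.geometry import HexElementSpec

logger = logging.getLogger(__name__)


class MechanicsError(ValueError):
    """Invalid mechanical parameter combination."""


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Meniscus:
    """A circular liquid bridge.

    Plate mode (two flat plates): give ``r_azi`` and exactly one of
    ``r_mer`` or ``gap_width`` (then ``r_mer = gap_width/(2 cos φ)``).
    Sphere mode (rigid sphere on a plate): give ``sphere_radius`` and
    ``filling_angle``; the curvature radii follow from the geometry.

    All lengths in metres, angles in radians, ``surface_tension`` in N/m.
    """

    surface_tension: float
    contact_angle: float = 0.0
    r_azi: Optional[float] = None
    r_mer: Optional[float] = None
    gap_width: Optional[float] = None
    sphere_radius: Optional[float] = None
    filling_angle: Optional[float] = None

    def __post_init__(self) -> None:
        if self.surface_tension <= 0:
            raise MechanicsError("surface_tension must be positive")
        if not 0 <= self.contact_angle < math.pi / 2:
            raise MechanicsError("contact_angle must lie in [0, π/2)")
        if self.r_mer is not None and self.gap_width is not None:
            raise MechanicsError("give either r_mer or gap_width, not both")
        for name in ("r_azi", "r_mer", "gap_width", "sphere_radius"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise MechanicsError(f"{name} must be positive")

    @property
    def meridional_radius(self) -> float:
        """Meridional curvature radius in plate mode [m]."""
        if self.r_mer is not None:
            return self.r_mer
        if self.gap_width is not None:
            return self.gap_width / (2.0 * math.cos(self.contact_angle))
        raise MechanicsError("plate mode requires r_mer or gap_width")


@dataclass(frozen=True)
class SqueezeFilm:
    """Viscous liquid film between pad and substrate.

    ``gap_rate`` is the signed rate of change of the gap width (positive
    while the surfaces separate). Optional fields select the model:
    ``plate_radius`` for plate–plate squeeze flow, ``sphere_radius`` for
    sphere–plate, ``area`` and ``sliding_speed`` for shear flow.
    """

    viscosity: float
    gap: float
    gap_rate: float = 0.0
    plate_radius: Optional[float] = None
    sphere_radius: Optional[float] = None
    area: Optional[float] = None
    sliding_speed: float = 0.0

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise MechanicsError("viscosity must be positive")
        if self.gap <= 0:
            raise MechanicsError("gap must be positive")


@dataclass(frozen=True)
class VdwContact:
    """Flat-plate van der Waals contact.

    ``effective_fraction`` scales the nominal area down to the portion in
    molecularly close contact (1 = full area).
    """

    hamaker: float
    gap: float
    area: float
    effective_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.hamaker <= 0:
            raise MechanicsError("hamaker must be positive")
        if self.gap <= 0:
            raise MechanicsError("gap must be positive")
        if self.area <= 0:
            raise MechanicsError("area must be positive")
        if not 0 < self.effective_fraction <= 1:
            raise MechanicsError("effective_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class LoadState:
    """Normal load on a sliding contact: weight component plus adhesion."""

    weight_component: float = 0.0
    adhesion: float = 0.0
    friction_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.friction_coefficient < 0:
            raise MechanicsError("friction_coefficient must be non-negative")

    @property
    def normal_load(self) -> float:
        return self.weight_component + self.adhesion


class LubricationRegime(str, enum.Enum):
    BOUNDARY = "boundary"
    MIXED = "mixed"
    ELASTOHYDRODYNAMIC = "elastohydrodynamic"
    HYDRODYNAMIC = "hydrodynamic"


_REGIME_ORDER = (
    LubricationRegime.BOUNDARY,
    LubricationRegime.MIXED,
    LubricationRegime.ELASTOHYDRODYNAMIC,
    LubricationRegime.HYDRODYNAMIC,
)

#: Default Stribeck cutpoints [m]. The Stribeck diagram for toe pads is
#: qualitative — no numeric thresholds are established — so these defaults
#: are placeholders spanning plausible decades and should be overridden
#: when calibration data exist.
DEFAULT_STRIBECK_THRESHOLDS = (1e-10, 1e-8, 1e-6)


@dataclass(frozen=True)
class LubricationState:
    """A Stribeck number together with its classified regime."""

    stribeck: float
    regime: LubricationRegime
    thresholds: tuple = DEFAULT_STRIBECK_THRESHOLDS


class DrainageRegime(str, enum.Enum):
    FAR = "far"
    INTERMEDIATE = "intermediate"
    NEAR = "near"


@dataclass(frozen=True)
class Material:
    """Linear-elastic pad material."""

    youngs_modulus: float
    poisson: float

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise MechanicsError("youngs_modulus must be positive")
        if not -1 < self.poisson <= 0.5:
            raise MechanicsError("poisson ratio must lie in (-1, 0.5]")

    @property
    def effective_modulus(self) -> float:
        return effective_modulus(self.youngs_modulus, self.poisson)


# ---------------------------------------------------------------------------
# capillary forces
# ---------------------------------------------------------------------------


def capillary_plate(meniscus: Meniscus) -> float:
    """Capillary adhesion of a circular bridge between two flat plates [N].

    ``F = 2π R_azi γ sin φ + π R_azi² γ (1/R_mer − 1/R_azi)``; the first
    term is the direct pull of surface tension along the contact line, the
    second the Laplace under-pressure across the meniscus. Positive means
    attractive; a convex bridge (``R_mer ≥ R_azi`` at φ = 0) can yield a
    non-positive value, which is returned as-is.
    """
    if meniscus.r_azi is None:
        raise MechanicsError("plate mode requires r_azi")
    gamma = meniscus.surface_tension
    phi = meniscus.contact_angle
    r_azi = meniscus.r_azi
    r_mer = meniscus.meridional_radius
    line_term = 2.0 * math.pi * r_azi * gamma * math.sin(phi)
    laplace_term = math.pi * r_azi**2 * gamma * (1.0 / r_mer - 1.0 / r_azi)
    force = line_term + laplace_term
    if force <= 0:
        logger.info(
            "non-attractive capillary bridge (R_mer=%.3g m >= R_azi=%.3g m)",
            r_mer,
            r_azi,
        )
    return force


def capillary_sphere(meniscus: Meniscus) -> float:
    """Capillary adhesion between a rigid sphere and a flat plate [N].

    With filling angle β and equal contact angles φ the curvature radii are
    ``R_mer = R(1−cos β)/(2c)`` with ``c = [cos(φ+β)+cos φ]/2`` and
    ``R_azi = R sin β − R_mer[1 − sin(φ+β)]``; the force is the sphere
    analogue of the plate law. For β, φ → 0 it converges to ``4πRγ``.
    """
    if meniscus.sphere_radius is None or meniscus.filling_angle is None:
        raise MechanicsError("sphere mode requires sphere_radius and filling_angle")
    gamma = meniscus.surface_tension
    phi = meniscus.contact_angle
    beta = meniscus.filling_angle
    radius = meniscus.sphere_radius
    if beta <= 0:
        raise MechanicsError("filling_angle must be positive")
    c = (math.cos(phi + beta) + math.cos(phi)) / 2.0
    if c <= 0:
        raise MechanicsError("invalid meniscus geometry (c <= 0)")
    r_mer = radius * (1.0 - math.cos(beta)) / (2.0 * c)
    r_azi = radius * math.sin(beta) - r_mer * (1.0 - math.sin(phi + beta))
    if r_azi <= 0:
        raise MechanicsError("invalid meniscus geometry (r_azi <= 0)")
    line_term = 2.0 * math.pi * radius * math.sin(beta) * gamma * math.sin(phi + beta)
    laplace_term = (
        math.pi
        * radius**2
        * math.sin(beta) ** 2
        * gamma
        * (1.0 / r_mer - 1.0 / r_azi)
    )
    return line_term + laplace_term


def capillary_sphere_limit(sphere_radius: float, surface_tension: float) -> float:
    """Small-angle limit ``4πRγ`` of the sphere–plate capillary force [N]."""
    return 4.0 * math.pi * sphere_radius * surface_tension


def capillary_length(surface_tension: float, density: float, gravity: float) -> float:
    """Capillary length ``κ = sqrt(γ/(ρ g))`` [m].

    Bounds the height up to which a concave meniscus can stand against
    gravity; ≈ 2.7 mm for water.
    """
    if surface_tension <= 0 or density <= 0 or gravity <= 0:
        raise MechanicsError("surface_tension, density, gravity must be positive")
    return math.sqrt(surface_tension / (density * gravity))


# ---------------------------------------------------------------------------
# hydrodynamic forces
# ---------------------------------------------------------------------------


def squeeze_film_plate(film: SqueezeFilm) -> float:
    """Stefan adhesion between two flat plates, signed [N].

    ``F = −(∂d/∂t)(3/2)π μ r_p⁴/d³``: negative while the gap opens
    (resisting separation, i.e. adhesive), positive while it closes.
    """
    if film.plate_radius is None:
        raise MechanicsError("plate squeeze film requires plate_radius")
    return (
        -film.gap_rate
        * 1.5
        * math.pi
        * film.viscosity
        * film.plate_radius**4
        / film.gap**3
    )


def squeeze_film_sphere(film: SqueezeFilm) -> float:
    """Squeeze-film force between a sphere and a plate, signed [N].

    ``F = −(∂d/∂t)·6π μ R²/d``.
    """
    if film.sphere_radius is None:
        raise MechanicsError("sphere squeeze film requires sphere_radius")
    return (
        -film.gap_rate * 6.0 * math.pi * film.viscosity * film.sphere_radius**2 / film.gap
    )


def adhesive_magnitude(signed_force: float) -> float:
    """Adhesive magnitude of a signed squeeze-film force (0 if repulsive)."""
    return max(0.0, -signed_force)


def shear_film_friction(film: SqueezeFilm) -> float:
    """Hydrodynamic friction of free shear flow, ``F = μ A v∥/d`` [N].

    Assumes a linear velocity profile across the gap; only valid for gaps
    wide enough to sustain free shear flow.
    """
    if film.area is None:
        raise MechanicsError("shear film requires area")
    return film.viscosity * film.area * film.sliding_speed / film.gap


def gap_for_shear_stress(viscosity: float, sliding_speed: float, shear_stress: float) -> float:
    """Gap width at which free shear flow would produce a given stress [m].

    Inverts ``σ = μ v∥/d``. Used to show that measured shear stresses
    would require sub-molecular gaps, ruling out free shear flow as the
    sole friction mechanism.
    """
    if shear_stress <= 0:
        raise MechanicsError("shear_stress must be positive")
    return viscosity * sliding_speed / shear_stress


# ---------------------------------------------------------------------------
# van der Waals and dry friction
# ---------------------------------------------------------------------------


def vdw_adhesion(contact: VdwContact) -> float:
    """Macroscopic van der Waals attraction between flat plates [N].

    ``|F| = f_eff · A · A_H/(6π d³)``, reported positive (attractive).
    """
    return (
        contact.effective_fraction
        * contact.area
        * contact.hamaker
        / (6.0 * math.pi * contact.gap**3)
    )


def hamaker_lower_bound(temperature: float, boltzmann: float = 1.4e-23) -> float:
    """Thermal lower bound ``0.7 k_B T`` on the Hamaker constant [J].

    Applies to two similar materials interacting across water, where only
    the zero-frequency (entropic) term survives.
    """
    if temperature <= 0:
        raise MechanicsError("temperature must be positive")
    return 0.7 * boltzmann * temperature


def coulomb_friction(load: LoadState) -> float:
    """Dry (Coulomb) friction ``F = μ∥ (F⊥,g + F⊥)`` [N]."""
    return load.friction_coefficient * load.normal_load


# ---------------------------------------------------------------------------
# lubrication and drainage
# ---------------------------------------------------------------------------


def stribeck_number(viscosity: float, sliding_speed: float, load_per_area: float) -> float:
    """Stribeck number ``St = μ v∥ / (F⊥,L/A)``.

    Uses the dynamic viscosity in the numerator (Hersey form). With
    pressure in Pa the group carries units of metres; only its position
    relative to the regime cutpoints matters.
    """
    if viscosity <= 0 or sliding_speed < 0:
        raise MechanicsError("viscosity must be positive and sliding_speed non-negative")
    if load_per_area <= 0:
        raise MechanicsError("load_per_area must be positive")
    return viscosity * sliding_speed / load_per_area


def classify_lubrication(
    stribeck: float,
    thresholds: Sequence[float] = DEFAULT_STRIBECK_THRESHOLDS,
) -> LubricationRegime:
    """Map a Stribeck number onto a lubrication regime.

    Regimes in increasing St: boundary, mixed, elastohydrodynamic,
    hydrodynamic. A value exactly at a cutpoint belongs to the lower
    regime (closed-left intervals).
    """
    thresholds = tuple(thresholds)
    if len(thresholds) != 3 or not all(
        a < b for a, b in zip(thresholds, thresholds[1:])
    ) or thresholds[0] <= 0:
        raise MechanicsError("thresholds must be three strictly increasing positive values")
    idx = sum(stribeck > t for t in thresholds)
    return _REGIME_ORDER[idx]


def drainage_crossover(cell: HexElementSpec) -> float:
    """Gap width at which drainage shifts from radial to channel flow [m].

    ``d₀ = w_c (h_c/(w_c + d_c))^(1/3)`` for a surface patterned with
    elements of diameter ``d_c``, height ``h_c`` and channel width ``w_c``;
    ≈ 1 µm for the toe-pad epidermal cells.
    """
    return cell.channel_width * (
        cell.height / (cell.channel_width + cell.diameter)
    ) ** (1.0 / 3.0)


def classify_drainage(gap: float, crossover: float, factor: float = 3.0) -> DrainageRegime:
    """Classify the drainage regime of a channelled contact.

    ``far`` when the gap exceeds the crossover by more than ``factor``
    (radial squeeze-out through the gap), ``near`` when it is below the
    crossover by more than ``factor`` (flow beneath single elements
    dominates), ``intermediate`` otherwise (channel flow dominates).
    """
    if gap <= 0 or crossover <= 0:
        raise MechanicsError("gap and crossover must be positive")
    if factor <= 1:
        raise MechanicsError("factor must exceed 1")
    if gap > factor * crossover:
        return DrainageRegime.FAR
    if gap < crossover / factor:
        return DrainageRegime.NEAR
    return DrainageRegime.INTERMEDIATE


# ---------------------------------------------------------------------------
# elasticity
# ---------------------------------------------------------------------------


def effective_modulus(youngs_modulus: float, poisson: float) -> float:
    """Plane-strain effective modulus ``E* = E/(1 − ν²)`` [Pa]."""
    if youngs_modulus <= 0:
        raise MechanicsError("youngs_modulus must be positive")
    if not -1 < poisson <= 0.5:
        raise MechanicsError("poisson ratio must lie in (-1, 0.5]")
    return youngs_modulus / (1.0 - poisson**2)
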