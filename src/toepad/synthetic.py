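"""Seeded generators of synthetic frog populations and trials.

The generators emulate the statistical structure that the allometric and
inversion analyses assume, so every downstream stage of the package can be
exercised and validated without any external data:

* a population of frogs whose total pad area follows a power law of
  snout–vent length with log-normal scatter, and whose body mass scales
  volumetrically;
* rotating-platform trials produced by inverting the inclined-plane
  statics for known ("ground-truth") tenacity and shear stress, with
  additive Gaussian angle noise;
* spherical-indentation trials produced from a ground-truth tenacity with
  multiplicative Gaussian force noise.

All randomness flows through explicit integer seeds; identical specs give
byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

_G_STANDARD = 9.81


class SyntheticError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class PopulationSpec:
    """A synthetic frog population.

    Lengths in mm, mass prefactor in g/mm^mass_exponent, area prefactor in
    mm²/mm^area_exponent. Defaults: pad area approximately quadratic in
    snout–vent length (the middle of the reported 1.76–2.29 range) and
    mass volumetric (exponent 3); prefactors put a 50 mm frog at ~10 g
    body mass and ~100 mm² total pad area, typical of mid-sized hylids.
    ``lognormal_sd`` is the standard deviation of the log-residual of both
    area and mass.
    """

    n: int = 50
    svl_range: Tuple[float, float] = (20.0, 80.0)  # [mm]
    area_exponent: float = 2.0
    area_prefactor: float = 0.04  # [mm² / mm^k]
    mass_exponent: float = 3.0
    mass_prefactor: float = 8e-5  # [g / mm^k]
    lognormal_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise SyntheticError("population needs at least three frogs")
        if not 0 < self.svl_range[0] < self.svl_range[1]:
            raise SyntheticError("svl_range must be increasing and positive")
        if self.lognormal_sd < 0:
            raise SyntheticError("lognormal_sd must be non-negative")


@dataclass(frozen=True)
class TrialSpec:
    """Ground truth and noise model for synthetic measurement trials.

    Stresses in mN mm⁻² (the values reported for real pads fall in
    roughly 0.2–1.5 for tenacity and 1–2 for shear stress); angle noise is
    additive Gaussian in degrees, force noise multiplicative Gaussian with
    the given coefficient of variation.
    """

    tenacity: float = 1.0  # [mN mm⁻²]
    shear_stress: float = 1.5  # [mN mm⁻²]
    angle_noise_sd: float = 2.0  # [deg]
    force_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tenacity < 0 or self.shear_stress < 0:
            raise SyntheticError("ground-truth stresses must be non-negative")
        if self.angle_noise_sd < 0 or self.force_noise_cv < 0:
            raise SyntheticError("noise parameters must be non-negative")


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Generate a morphometrics table.

    Columns: ``svl_mm``, ``mass_g``, ``pad_area_mm2``. Area and mass
    follow ``a·ℓ^k·exp(ε)`` with independent ``ε ~ N(0, lognormal_sd²)``;
    snout–vent lengths are log-uniform over the spec range so both ends of
    the size range are equally represented on the fitting axes.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.svl_range
    svl = np.exp(rng.uniform(math.log(lo), math.log(hi), spec.n))
    eps_area = rng.normal(0.0, spec.lognormal_sd, spec.n)
    eps_mass = rng.normal(0.0, spec.lognormal_sd, spec.n)
    area = spec.area_prefactor * svl**spec.area_exponent * np.exp(eps_area)
    mass = spec.mass_prefactor * svl**spec.mass_exponent * np.exp(eps_mass)
    return pd.DataFrame({"svl_mm": svl, "mass_g": mass, "pad_area_mm2": area})


def generate_incline_trials(
    population: pd.DataFrame,
    spec: TrialSpec,
    gravity: float = _G_STANDARD,
) -> pd.DataFrame:
    """Generate rotating-platform trials for a population.

    Per frog, the noiseless angles invert the inclined-plane statics:
    ``α∥ = arcsin(min(1, σ∥ A/(m g)))`` and
    ``α⊥ = arccos(−min(1, σ⊥ A/(m g)))``. Gaussian angle noise is added
    and the result clipped to [0°, 180°]. Frogs whose adhesion exceeds
    their weight (``σ⊥ A ≥ m g``) can never fall and are flagged with
    ``can_fall = False`` and ``fall_angle_deg = 180``.

    Returns columns ``mass_kg``, ``pad_area_mm2``, ``slip_angle_deg``,
    ``fall_angle_deg``, ``can_fall``.
    """
    rng = np.random.default_rng(spec.seed)
    mass_kg = population["mass_g"].to_numpy() * 1e-3
    area_mm2 = population["pad_area_mm2"].to_numpy()
    weight = mass_kg * gravity  # [N]
    # stress [mN mm⁻²] × area [mm²] = force [mN]; ×1e-3 → N
    shear_force = spec.shear_stress * 1e-3 * area_mm2
    normal_force = spec.tenacity * 1e-3 * area_mm2

    slip = np.degrees(np.arcsin(np.minimum(1.0, shear_force / weight)))
    ratio = normal_force / weight
    can_fall = ratio < 1.0
    fall = np.degrees(np.arccos(-np.minimum(1.0, ratio)))

    if spec.angle_noise_sd > 0:
        slip = slip + rng.normal(0.0, spec.angle_noise_sd, slip.size)
        fall = fall + rng.normal(0.0, spec.angle_noise_sd, fall.size)
    slip = np.clip(slip, 0.0, 180.0)
    fall = np.clip(fall, 0.0, 180.0)
    fall = np.where(can_fall, fall, 180.0)
    # noise must not push the slip angle past the fall angle
    slip = np.minimum(slip, fall)

    return pd.DataFrame(
        {
            "mass_kg": mass_kg,
            "pad_area_mm2": area_mm2,
            "slip_angle_deg": slip,
            "fall_angle_deg": fall,
            "can_fall": can_fall,
        }
    )


def generate_indentation_trials(
    spec: TrialSpec,
    n: int,
    seed: Optional[int] = None,
    indenter_radius: float = 1.5e-3,
    depth_range: Tuple[float, float] = (50e-6, 350e-6),
) -> pd.DataFrame:
    """Generate spherical-indentation pull-off trials.

    Depths are sampled uniformly over ``depth_range`` (default 50–350 µm,
    the protocol range for a 1.5 mm indenter on whole pads); forces are
    ``σ⊥ · 2π d_i r_i`` with multiplicative Gaussian noise of coefficient
    of variation ``force_noise_cv``.

    Returns columns ``pull_off_force_N``, ``indenter_radius_m``,
    ``indentation_depth_m``.
    """
    if n < 1:
        raise SyntheticError("need at least one trial")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    depth = rng.uniform(depth_range[0], depth_range[1], n)
    force = spec.tenacity * 1e3 * 2.0 * math.pi * depth * indenter_radius
    if spec.force_noise_cv > 0:
        force = force * (1.0 + rng.normal(0.0, spec.force_noise_cv, n))
    return pd.DataFrame(
        {
            "pull_off_force_N": force,
            "indenter_radius_m": np.full(n, indenter_radius),
            "indentation_depth_m": depth,
        }
    )
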