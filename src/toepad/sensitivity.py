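"""Sensitivity sweeps of capillary and van der Waals tenacities.

A *tenacity* is an attachment force per unit nominal pad area, expressed
here in mN mm⁻² (numerically equal to kPa). The module sweeps the two
adhesion models over 2-D parameter grids spanning several decades, masks
the region compatible with a measured tenacity band, and provides the
closed-form inversions behind the headline predictions: the critical
van der Waals gap width for a target tenacity, and the meniscus curvature
radius implied by the measured tenacity band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from skimage import measure as _skmeasure

from toepad.mechanics import Meniscus, MechanicsError, capillary_plate

logger = logging.getLogger(__name__)

#: Pa -> mN mm⁻²
_PA_TO_MN_MM2 = 1e-3


@dataclass(frozen=True)
class Axis:
    """One grid axis: a named, optionally log-spaced range."""

    name: str
    lo: float
    hi: float
    n: int
    log: bool = True

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("axis requires lo < hi")
        if self.n < 2:
            raise ValueError("axis requires at least two points")
        if self.log and self.lo <= 0:
            raise ValueError("log axis requires positive bounds")

    def values(self) -> np.ndarray:
        if self.log:
            return np.logspace(math.log10(self.lo), math.log10(self.hi), self.n)
        return np.linspace(self.lo, self.hi, self.n)


@dataclass(frozen=True)
class SweepGrid:
    """A 2-D parameter grid (x varies along columns, y along rows)."""

    x: Axis
    y: Axis

    def mesh(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x.values(), self.y.values())


@dataclass(frozen=True)
class TenacityField:
    """Tenacity evaluated on a sweep grid [mN mm⁻²]."""

    grid: SweepGrid
    values: np.ndarray
    model_id: str

    def __post_init__(self) -> None:
        expected = (self.grid.y.n, self.grid.x.n)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != grid shape {expected}")


@dataclass(frozen=True)
class FeasibleRegion:
    """Grid cells whose tenacity lies within a measured band."""

    mask: np.ndarray
    sigma_lo: float
    sigma_hi: float
    boundary: List[np.ndarray] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


def sweep_capillary(
    grid: SweepGrid,
    surface_tension: float,
    contact_angle: float = 0.0,
) -> TenacityField:
    """Capillary plate–plate tenacity over an (R_mer, R_azi) grid.

    x axis: meridional radius R_mer [m]; y axis: azimuthal radius
    R_azi [m]. Tenacity is the bridge force divided by the meniscus
    footprint ``π R_azi²``. Points with ``R_mer ≥ R_azi`` produce a
    non-attractive bridge and are kept as computed (may be ≤ 0).
    """
    r_mer, r_azi = grid.mesh()
    values = np.empty_like(r_mer)
    flagged = 0
    for idx in np.ndindex(values.shape):
        m = Meniscus(
            surface_tension=surface_tension,
            contact_angle=contact_angle,
            r_azi=float(r_azi[idx]),
            r_mer=float(r_mer[idx]),
        )
        force = capillary_plate(m)
        if force <= 0:
            flagged += 1
        values[idx] = force / (math.pi * r_azi[idx] ** 2) * _PA_TO_MN_MM2
    if flagged:
        logger.info("%d grid points have a non-attractive bridge (R_mer >= R_azi)", flagged)
    return TenacityField(grid=grid, values=values, model_id="capillary_plate")


def sweep_vdw(grid: SweepGrid, effective_fraction: float = 1.0) -> TenacityField:
    """Van der Waals tenacity over an (A_H, d_g) grid.

    x axis: Hamaker constant A_H [J]; y axis: gap width d_g [m].
    Tenacity = ``f_eff A_H/(6π d_g³)``.
    """
    if not 0 < effective_fraction <= 1:
        raise MechanicsError("effective_fraction must lie in (0, 1]")
    hamaker, gap = grid.mesh()
    values = effective_fraction * hamaker / (6.0 * math.pi * gap**3) * _PA_TO_MN_MM2
    return TenacityField(grid=grid, values=values, model_id="vdw")


def feasible_region(field: TenacityField, sigma_lo: float, sigma_hi: float) -> FeasibleRegion:
    """Mask the grid cells whose tenacity lies in [σ_lo, σ_hi] mN mm⁻².

    The band boundary is extracted by marching squares with linear
    interpolation (one polyline per iso-level and connected component, in
    fractional row/column grid coordinates).
    """
    if not sigma_lo < sigma_hi:
        raise ValueError("requires sigma_lo < sigma_hi")
    mask = (field.values >= sigma_lo) & (field.values <= sigma_hi)
    boundary: List[np.ndarray] = []
    if mask.any():
        for level in (sigma_lo, sigma_hi):
            vmin, vmax = field.values.min(), field.values.max()
            if vmin < level < vmax:
                boundary.extend(_skmeasure.find_contours(field.values, level))
    else:
        logger.warning("feasible region is empty for band [%g, %g]", sigma_lo, sigma_hi)
    return FeasibleRegion(mask=mask, sigma_lo=sigma_lo, sigma_hi=sigma_hi, boundary=boundary)


def critical_gap_vdw(sigma_target: float, hamaker: float, effective_fraction: float = 1.0) -> float:
    """Gap width at which the vdW tenacity equals a target [m].

    Inverts ``σ = f_eff A_H/(6π d³)``: ``d = (f_eff A_H/(6π σ))^(1/3)``.
    ``sigma_target`` in Pa.
    """
    if sigma_target <= 0 or hamaker <= 0 or effective_fraction <= 0:
        raise MechanicsError("all arguments must be positive")
    return (effective_fraction * hamaker / (6.0 * math.pi * sigma_target)) ** (1.0 / 3.0)


def predict_meniscus_curvature(sigma_lo: float, sigma_hi: float, surface_tension: float) -> float:
    """Meniscus curvature radius implied by a measured tenacity band [m].

    In the Laplace-dominated limit (φ = 0, R_azi ≫ R_mer) the tenacity is
    ``γ/R_mer``; the band's representative tenacity is taken as the
    geometric mean of its edges (bands from log-spaced sweeps are
    symmetric about it), giving ``R_mer = γ/√(σ_lo σ_hi)``.
    Inputs in Pa and N/m.
    """
    if not 0 < sigma_lo <= sigma_hi:
        raise MechanicsError("requires 0 < sigma_lo <= sigma_hi")
    sigma_rep = math.sqrt(sigma_lo * sigma_hi)
    return surface_tension / sigma_rep
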