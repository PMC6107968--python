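"""Geometrical model of the ventral toe-pad epidermis.

The ventral surface of a tree-frog toe pad is idealised as a circular disc
tiled by regular hexagonal epidermal cells separated by microchannels; the
apical face of every cell is in turn tiled by regular hexagonal nanopillars
separated by nanochannels, each pillar carrying a circular apical dimple.
From a parametric description of the two tiling levels the model derives
element counts, the enhancement of the liquid-accessible ("wetted") surface
relative to a smooth pad, and the partition of the projected pad area into
channel network, dimples, and potential full-contact surface.

Conventions
-----------
* Hexagon ``diameter`` is the across-corners (vertex-to-vertex) width, so
  the edge length is ``diameter / 2`` and the across-flats width is
  ``(√3/2)·diameter``.
* The unit tile of a hexagonal tiling with across-flats width ``f`` and
  channel width ``w`` has lattice pitch ``f + w`` and area
  ``(√3/2)(f + w)²``; counts use infinite-lattice density × region area,
  rounded to the nearest integer (the pad is ~360 cell diameters across,
  so the neglected boundary term is far below the rounding error).
* The wetted surface of a tiling level is its full projected area
  (hexagon tops plus channel floors) plus the lateral channel-wall area,
  counted once per element at its full perimeter.
* All stored lengths are SI metres; convenience display conversions are
  applied only at serialisation time.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

logger = logging.getLogger(__name__)

_SQRT3 = math.sqrt(3.0)


class GeometryError(ValueError):
    """Invalid geometric specification."""


@dataclass(frozen=True)
class HexElementSpec:
    """One level of the hexagonal surface pattern (cell or nanopillar).

    Parameters
    ----------
    diameter
        Across-corners width of the regular hexagon [m].
    height
        Height of the prismatic element, i.e. channel depth [m]. May be
        zero (a flat pattern with no walls).
    channel_width
        Width of the channel separating neighbouring elements [m].
    dimple_diameter
        Diameter of the circular apical dimple, if present [m].
    """

    diameter: float
    height: float
    channel_width: float
    dimple_diameter: Optional[float] = None

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.channel_width <= 0:
            raise GeometryError("diameter and channel_width must be positive")
        if self.height < 0:
            raise GeometryError("height must be non-negative")
        if self.channel_width >= self.diameter:
            raise GeometryError("channel_width must be smaller than the element diameter")
        if self.dimple_diameter is not None:
            if self.dimple_diameter <= 0:
                raise GeometryError("dimple_diameter must be positive when given")
            if self.dimple_diameter >= self.across_flats:
                raise GeometryError(
                    "dimple_diameter must be smaller than the across-flats width"
                )

    @property
    def edge_length(self) -> float:
        """Hexagon edge length, ``diameter / 2`` [m]."""
        return self.diameter / 2.0

    @property
    def across_flats(self) -> float:
        """Flat-to-flat width ``(√3/2)·diameter`` [m]."""
        return (_SQRT3 / 2.0) * self.diameter

    @property
    def apical_area(self) -> float:
        """Area of the hexagonal top face, ``(3√3/2)·a²`` [m²]."""
        return (3.0 * _SQRT3 / 2.0) * self.edge_length**2

    @property
    def perimeter(self) -> float:
        """Hexagon perimeter, ``6a = 3·diameter`` [m]."""
        return 6.0 * self.edge_length

    @property
    def pitch(self) -> float:
        """Lattice spacing between neighbouring element centres [m]."""
        return self.across_flats + self.channel_width

    @property
    def tile_area(self) -> float:
        """Area of the unit tile (hexagon plus its share of channel) [m²]."""
        return (_SQRT3 / 2.0) * self.pitch**2

    @property
    def wall_area(self) -> float:
        """Lateral channel-wall area contributed by one element [m²]."""
        return self.perimeter * self.height

    @property
    def dimple_area(self) -> float:
        """Area of the circular apical dimple (0 when absent) [m²]."""
        if self.dimple_diameter is None:
            return 0.0
        return math.pi * self.dimple_diameter**2 / 4.0


@dataclass(frozen=True)
class PadGeometry:
    """A circular pad carrying the two-level hexagonal pattern.

    ``pillar`` may be ``None`` to model a cells-only surface (no
    nanopillar tiling on the cell tops).
    """

    pad_diameter: float
    cell: HexElementSpec
    pillar: Optional[HexElementSpec] = None

    def __post_init__(self) -> None:
        if self.pad_diameter <= 0:
            raise GeometryError("pad_diameter must be positive")
        if self.pad_diameter <= 10 * self.cell.diameter:
            raise GeometryError("pad must be much larger than a single cell")
        if self.pillar is not None and self.pillar.pitch > self.cell.diameter:
            raise GeometryError("pillar pitch must not exceed the cell diameter")


@dataclass(frozen=True)
class AreaBudget:
    """Counts, wetted-area folds, and area fractions of a pad surface.

    ``frac_channels_total + frac_dimple + frac_full_contact == 1`` by
    construction; the full-contact fraction is the remainder of the
    projected area not occupied by channels (either level) or dimples.
    """

    projected_area: float  # [m²]
    n_cells: int
    n_pillars: int
    pillars_per_cell: int
    pillar_density: float  # [m⁻²]
    wetted_fold_cells: float
    wetted_fold_total: float
    frac_microchannel: float
    frac_channels_total: float
    frac_dimple: float
    frac_full_contact: float

    def to_dict(self) -> dict:
        """Serialisable summary in display units (mm², mm⁻²)."""
        return {
            "projected_area_mm2": self.projected_area * 1e6,
            "n_cells": self.n_cells,
            "n_pillars": self.n_pillars,
            "pillars_per_cell": self.pillars_per_cell,
            "pillar_density_per_mm2": self.pillar_density * 1e-6,
            "wetted_fold_cells": self.wetted_fold_cells,
            "wetted_fold_total": self.wetted_fold_total,
            "frac_microchannel": self.frac_microchannel,
            "frac_channels_total": self.frac_channels_total,
            "frac_dimple": self.frac_dimple,
            "frac_full_contact": self.frac_full_contact,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_csv_row(self) -> str:
        """One header line plus one data line, comma separated."""
        d = self.to_dict()
        header = ",".join(d)
        values = ",".join(repr(v) if isinstance(v, float) else str(v) for v in d.values())
        return f"{header}\n{values}\n"


def projected_pad_area(pad_diameter: float) -> float:
    """Projected ventral area of a circular pad, ``π d²/4`` [m²]."""
    if pad_diameter <= 0:
        raise GeometryError("pad_diameter must be positive")
    return math.pi * pad_diameter**2 / 4.0


def tile_count(region_area: float, element: HexElementSpec) -> int:
    """Number of hexagonal elements tiling a region of given area.

    Uses the infinite-lattice density (one element per unit tile) times the
    region area, rounded to the nearest integer. Valid when the region is
    much larger than a tile; for the default pad the neglected boundary
    term is below 0.1 %.
    """
    if region_area <= 0:
        raise GeometryError("region_area must be positive")
    return round(region_area / element.tile_area)


def area_budget(geometry: PadGeometry) -> AreaBudget:
    """Derive the full area budget of a pad surface.

    Wetted-area folds are expressed relative to a smooth pad of the same
    projected area. The channel fraction at the nanoscale counts, per cell
    top, the projected area between pillar hexagons; dimples are circular
    holes in the pillar tops. Whatever projected area is not channel or
    dimple is potential full-contact surface.
    """
    cell = geometry.cell
    pillar = geometry.pillar

    a_pad = projected_pad_area(geometry.pad_diameter)
    n_cells = tile_count(a_pad, cell)

    tile_c = cell.tile_area
    # Per unit tile: full projected area (hexagon top + channel floor)
    # plus the cell's channel-wall area.
    wetted_cells_per_tile = tile_c + cell.wall_area
    fold_cells = wetted_cells_per_tile / tile_c

    frac_micro = (tile_c - cell.apical_area) / tile_c

    if pillar is None:
        pillars_per_cell = 0
        n_pillars = 0
        fold_total = fold_cells
        frac_channels_total = frac_micro
        frac_dimple = 0.0
    else:
        pillars_per_cell = tile_count(cell.apical_area, pillar)
        n_pillars = n_cells * pillars_per_cell
        fold_total = (
            wetted_cells_per_tile + pillars_per_cell * pillar.wall_area
        ) / tile_c
        nano_channel_per_tile = cell.apical_area - pillars_per_cell * pillar.apical_area
        frac_channels_total = frac_micro + nano_channel_per_tile / tile_c
        if pillar.dimple_diameter is None:
            logger.warning("pillar spec has no dimple; dimple fraction set to 0")
            frac_dimple = 0.0
        else:
            frac_dimple = pillars_per_cell * pillar.dimple_area / tile_c

    frac_full_contact = 1.0 - frac_channels_total - frac_dimple

    return AreaBudget(
        projected_area=a_pad,
        n_cells=n_cells,
        n_pillars=n_pillars,
        pillars_per_cell=pillars_per_cell,
        pillar_density=n_pillars / a_pad,
        wetted_fold_cells=fold_cells,
        wetted_fold_total=fold_total,
        frac_microchannel=frac_micro,
        frac_channels_total=frac_channels_total,
        frac_dimple=frac_dimple,
        frac_full_contact=frac_full_contact,
    )


def default_geometry() -> PadGeometry:
    """Reference toe-pad geometry of an adult hylid tree frog.

    Pad diameter 3.6 mm; epidermal cells 10 µm across, 10 µm tall, 1 µm
    channels; nanopillars 300 nm across, 300 nm tall, 100 nm channels,
    with 240 nm circular apical dimples.
    """
    return PadGeometry(
        pad_diameter=3.6e-3,
        cell=HexElementSpec(diameter=10e-6, height=10e-6, channel_width=1e-6),
        pillar=HexElementSpec(
            diameter=300e-9,
            height=300e-9,
            channel_width=100e-9,
            dimple_diameter=240e-9,
        ),
    )
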