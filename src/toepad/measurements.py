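"""Inversion of raw attachment observations and allometric fitting.

Covers the three standard observation types for whole-animal and
single-pad attachment:

* **Rotating platform.** A frog sits on a platform that is tilted until it
  slides (slip angle α∥) and until it falls (fall angle α⊥). Standard
  inclined-plane statics converts the angles into friction
  ``m g sin α∥`` and adhesion ``−m g cos α⊥`` (positive only past
  vertical, i.e. on an overhang).
* **Spherical indentation.** A sphere of radius ``r_i`` pressed to depth
  ``d_i`` touches the pad over a spherical cap of area ``2π d_i r_i``;
  dividing the pull-off force by that area yields a tenacity.
* **Allometry.** Attachment quantities scale as power laws of body size;
  exponents are estimated by ordinary least squares on log10–log10 axes
  with normal-theory confidence intervals.

The module also ships transcriptions of the published stiffness, adhesion
and friction performance tables as validated CSV fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

_G_STANDARD = 9.81


class MeasurementError(ValueError):
    """Invalid measurement record or inversion input."""


@dataclass(frozen=True)
class InclineTrial:
    """One rotating-platform trial.

    ``body_mass`` in kg, angles in degrees, optional total pad area in m².
    """

    body_mass: float
    slip_angle: float
    fall_angle: float
    pad_area: Optional[float] = None

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise MeasurementError("body_mass must be positive")
        if not 0 <= self.slip_angle <= self.fall_angle <= 180:
            raise MeasurementError("angles must satisfy 0 <= slip <= fall <= 180 deg")
        if self.pad_area is not None and self.pad_area <= 0:
            raise MeasurementError("pad_area must be positive when given")


@dataclass(frozen=True)
class InclineForces:
    """Forces (and stresses, when the pad area is known) from one trial."""

    friction: float  # [N]
    adhesion: float  # [N]; > 0 only on overhangs
    shear_stress: Optional[float] = None  # [Pa]
    tenacity: Optional[float] = None  # [Pa]
    measurable_adhesion: bool = True


@dataclass(frozen=True)
class IndentationTrial:
    """One spherical-indenter pull-off measurement (SI units)."""

    pull_off_force: float
    indenter_radius: float
    indentation_depth: float

    def __post_init__(self) -> None:
        if min(self.pull_off_force, self.indenter_radius, self.indentation_depth) <= 0:
            raise MeasurementError("all indentation quantities must be positive")
        if self.indentation_depth > 2 * self.indenter_radius:
            raise MeasurementError("indentation depth cannot exceed the sphere diameter")


@dataclass(frozen=True)
class ScalingFit:
    """Power-law fit ``y = prefactor · x^exponent``."""

    exponent: float
    prefactor: float
    pearson_r: float
    ci95: Tuple[float, float]
    n: int

    def covers(self, exponent: float) -> bool:
        """Whether the 95 % CI covers a hypothesised exponent."""
        return self.ci95[0] <= exponent <= self.ci95[1]


def forces_from_incline(trial: InclineTrial, gravity: float = _G_STANDARD) -> InclineForces:
    """Convert platform angles into friction and adhesion.

    Friction equals the downslope weight component at the slip angle,
    ``m g sin α∥``. Adhesion is the normal force needed at the fall angle,
    ``−m g cos α⊥``: zero at vertical, positive on overhangs, and negative
    (reported with ``measurable_adhesion=False`` rather than clamped) when
    the animal falls before vertical.
    """
    weight = trial.body_mass * gravity
    friction = weight * math.sin(math.radians(trial.slip_angle))
    adhesion = -weight * math.cos(math.radians(trial.fall_angle))
    shear = tenac = None
    if trial.pad_area is not None:
        shear = friction / trial.pad_area
        tenac = adhesion / trial.pad_area
    return InclineForces(
        friction=friction,
        adhesion=adhesion,
        shear_stress=shear,
        tenacity=tenac,
        measurable_adhesion=adhesion > 0,
    )


def tenacity_from_indentation(trial: IndentationTrial) -> float:
    """Tenacity from a spherical-cap contact, ``F/(2π d_i r_i)`` [Pa]."""
    return trial.pull_off_force / (
        2.0 * math.pi * trial.indentation_depth * trial.indenter_radius
    )


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> ScalingFit:
    """Fit ``y = a·x^k`` by OLS on log10–log10 axes.

    Returns the exponent ``k``, the prefactor ``a = 10^intercept``, the
    Pearson correlation of the logged data, and the normal-theory 95 %
    confidence interval of the exponent (t-distribution, n − 2 df).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MeasurementError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise MeasurementError("need at least three points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise MeasurementError("power-law fitting requires strictly positive data")
    res = stats.linregress(np.log10(x), np.log10(y))
    if res.stderr == 0:
        half = 0.0
    else:
        half = stats.t.ppf(0.975, x.size - 2) * res.stderr
    return ScalingFit(
        exponent=res.slope,
        prefactor=10.0**res.intercept,
        pearson_r=res.rvalue,
        ci95=(res.slope - half, res.slope + half),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# literature performance fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "stiffness": "stiffness.csv",
    "adhesion": "adhesion.csv",
    "friction": "friction.csv",
}

_FIXTURE_COLUMNS = [
    "source_ref",
    "species",
    "quantity",
    "value_lo",
    "value_hi",
    "units",
    "substrate",
    "remarks",
]

_QUANTITY_UNITS = {
    "E_star": "kPa",
    "adhesion": "mN",
    "tenacity": "mN_per_mm2",
    "friction": "mN",
    "shear_stress": "mN_per_mm2",
}


@dataclass(frozen=True)
class PerformanceRecord:
    """One published attachment-performance measurement.

    Ranges are stored as ``value_lo``/``value_hi``; single values carry the
    same number in both fields, with any reported spread in ``remarks``.
    """

    source_ref: str
    species: str
    quantity: str
    value_lo: float
    value_hi: float
    units: str
    substrate: str = ""
    remarks: str = ""

    def __post_init__(self) -> None:
        if self.quantity not in _QUANTITY_UNITS:
            raise MeasurementError(f"unknown quantity {self.quantity!r}")
        if self.units != _QUANTITY_UNITS[self.quantity]:
            raise MeasurementError(
                f"quantity {self.quantity!r} must carry units "
                f"{_QUANTITY_UNITS[self.quantity]!r}, got {self.units!r}"
            )
        if not self.value_lo <= self.value_hi:
            raise MeasurementError("value_lo must not exceed value_hi")


def load_fixtures(table_id: str) -> list[PerformanceRecord]:
    """Load one of the packaged performance tables.

    ``table_id`` is ``'stiffness'`` (effective elastic moduli),
    ``'adhesion'`` (pull-off forces and tenacities) or ``'friction'``
    (friction forces and shear stresses). Every row is schema-validated;
    a malformed row raises :class:`MeasurementError` naming it.
    """
    try:
        fname = _FIXTURE_FILES[table_id]
    except KeyError:
        raise MeasurementError(
            f"unknown table {table_id!r}; expected one of {sorted(_FIXTURE_FILES)}"
        ) from None
    with resources.files("toepad.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, dtype=str).fillna("")
    if list(df.columns) != _FIXTURE_COLUMNS:
        raise MeasurementError(f"fixture {fname} has unexpected columns {list(df.columns)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                PerformanceRecord(
                    source_ref=row["source_ref"],
                    species=row["species"],
                    quantity=row["quantity"],
                    value_lo=float(row["value_lo"]),
                    value_hi=float(row["value_hi"]),
                    units=row["units"],
                    substrate=row["substrate"],
                    remarks=row["remarks"],
                )
            )
        except (MeasurementError, ValueError) as exc:
            raise MeasurementError(f"fixture {fname}, row {i}: {exc}") from exc
    return records


def records_to_frame(records: Sequence[PerformanceRecord]) -> pd.DataFrame:
    """Tabular view of a record list (column order matches the fixtures)."""
    return pd.DataFrame([vars(r) for r in records], columns=_FIXTURE_COLUMNS)
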