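"""Configuration loading: unit-suffixed YAML maps to model objects."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from toepad import constants
from toepad.geometry import HexElementSpec, PadGeometry
from toepad.units import UnitError, parse_suffixed

_GEOMETRY_KEYS = {
    "pad_diameter",
    "cell_diameter",
    "cell_height",
    "cell_channel_width",
    "pillar_diameter",
    "pillar_height",
    "pillar_channel_width",
    "pillar_dimple_diameter",
}

_CONSTANT_DEFAULTS = {
    "surface_tension": constants.GAMMA_MUCUS,
    "viscosity": constants.MU_MUCUS,
    "contact_angle": constants.PHI_MUCUS,
    "gravity": constants.G_STANDARD,
    "density": constants.RHO_WATER,
    "boltzmann": constants.K_B,
    "temperature": constants.T_LAB,
}


class ConfigError(ValueError):
    """Malformed configuration file."""


def _load_yaml(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    return data


def load_geometry(path: Optional[Union[str, Path]] = None) -> PadGeometry:
    """Load a pad geometry from a unit-suffixed YAML file.

    With no path, the packaged default geometry is used. Unknown keys and
    keys without a recognised unit suffix are rejected.
    """
    if path is None:
        with resources.as_file(
            resources.files("toepad.data").joinpath("default_geometry.yaml")
        ) as p:
            raw = _load_yaml(p)
    else:
        raw = _load_yaml(path)
    try:
        si = parse_suffixed(raw)
    except UnitError as exc:
        raise ConfigError(str(exc)) from exc
    unknown = set(si) - _GEOMETRY_KEYS
    if unknown:
        raise ConfigError(f"unknown geometry keys: {sorted(unknown)}")
    missing = _GEOMETRY_KEYS - set(si) - {"pillar_dimple_diameter"}
    if missing:
        raise ConfigError(f"missing geometry keys: {sorted(missing)}")
    cell = HexElementSpec(
        diameter=si["cell_diameter"],
        height=si["cell_height"],
        channel_width=si["cell_channel_width"],
    )
    pillar = HexElementSpec(
        diameter=si["pillar_diameter"],
        height=si["pillar_height"],
        channel_width=si["pillar_channel_width"],
        dimple_diameter=si.get("pillar_dimple_diameter"),
    )
    return PadGeometry(pad_diameter=si["pad_diameter"], cell=cell, pillar=pillar)


def load_constants(path: Optional[Union[str, Path]] = None) -> dict:
    """Load physical constants, falling back to the packaged defaults.

    Returns a dict with keys ``surface_tension`` [N/m], ``viscosity``
    [Pa·s], ``contact_angle`` [rad], ``gravity`` [m/s²], ``density``
    [kg/m³], ``boltzmann`` [J/K], ``temperature`` [K].
    """
    values = dict(_CONSTANT_DEFAULTS)
    if path is not None:
        raw = _load_yaml(path)
        try:
            si = parse_suffixed(raw)
        except UnitError as exc:
            raise ConfigError(str(exc)) from exc
        unknown = set(si) - set(values)
        if unknown:
            raise ConfigError(f"unknown constant keys: {sorted(unknown)}")
        values.update(si)
    return values
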