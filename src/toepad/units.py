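"""Minimal unit handling via key suffixes.

Configuration files and CLI flags carry explicit unit suffixes
(``cell_diameter_um: 10``); internally everything is SI (m, m², N, Pa,
Pa·s, J, K, rad). This module owns the suffix → SI-factor table and the
parsing of suffixed key/value maps.
"""

from __future__ import annotations

import math

# suffix -> multiplicative factor to SI base units
_FACTORS: dict[str, float] = {
    # length
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "nm": 1e-9,
    # area
    "m2": 1.0,
    "mm2": 1e-6,
    "um2": 1e-12,
    # speed
    "m_per_s": 1.0,
    "mm_per_s": 1e-3,
    "um_per_s": 1e-6,
    # force
    "N": 1.0,
    "mN": 1e-3,
    "uN": 1e-6,
    "nN": 1e-9,
    # pressure / tenacity
    "Pa": 1.0,
    "kPa": 1e3,
    "mN_per_mm2": 1e3,  # 1 mN mm⁻² = 1 kPa
    # surface tension
    "N_per_m": 1.0,
    "mN_per_m": 1e-3,
    # viscosity
    "Pa_s": 1.0,
    "mPa_s": 1e-3,
    # energy
    "J": 1.0,
    # temperature
    "K": 1.0,
    # entropy-like (Boltzmann constant)
    "J_per_K": 1.0,
    # density
    "kg_per_m3": 1.0,
    # acceleration
    "m_per_s2": 1.0,
    # mass
    "kg": 1.0,
    "g": 1e-3,
    # angles (to radians)
    "rad": 1.0,
    "deg": math.pi / 180.0,
    # dimensionless passthrough
    "1": 1.0,
}

#: Factors for formatting SI values back into display units.
TO_MN_PER_MM2 = 1e-3  # Pa -> mN mm⁻²


class UnitError(ValueError):
    """A config key has an unknown or missing unit suffix."""


def split_key(key: str) -> tuple[str, str | None]:
    """Split ``cell_diameter_um`` into ``('cell_diameter', 'um')``.

    Tries the longest matching suffix (so ``gamma_mN_per_m`` resolves to
    ``mN_per_m`` and not ``m``). Returns ``(key, None)`` when no suffix
    matches.
    """
    parts = key.split("_")
    for i in range(1, len(parts)):
        suffix = "_".join(parts[i:])
        if suffix in _FACTORS:
            return "_".join(parts[:i]), suffix
    return key, None


def to_si(value: float, suffix: str) -> float:
    """Convert ``value`` expressed in ``suffix`` units to SI."""
    try:
        return float(value) * _FACTORS[suffix]
    except KeyError:
        raise UnitError(f"unknown unit suffix {suffix!r}") from None


def parse_suffixed(mapping: dict[str, float], *, require_units: bool = True) -> dict[str, float]:
    """Convert a flat ``{key_with_suffix: value}`` map to ``{key: SI value}``.

    Parameters
    ----------
    mapping
        Flat map whose keys end in a unit suffix from the supported table.
    require_units
        When True (default), a key without a recognised suffix raises
        :class:`UnitError`; otherwise it is passed through unchanged.
    """
    out: dict[str, float] = {}
    for key, value in mapping.items():
        base, suffix = split_key(key)
        if suffix is None:
            if require_units:
                raise UnitError(f"key {key!r} carries no recognised unit suffix")
            out[key] = value
        else:
            if base in out:
                raise UnitError(f"duplicate parameter {base!r} (conflicting unit suffixes)")
            out[base] = to_si(value, suffix)
    return out
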