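import math

import pytest

from toepad.geometry import HexElementSpec, PadGeometry, default_geometry


@pytest.fixture(scope="session")
def reference_geometry() -> PadGeometry:
    """The adult-frog reference pad (3.6 mm pad, 10 µm cells, 300 nm pillars)."""
    return default_geometry()


@pytest.fixture(scope="session")
def reference_cell() -> HexElementSpec:
    return default_geometry().cell


def enumerate_hex_lattice_in_disc(disc_radius: float, pitch: float) -> int:
    """Brute-force oracle: count triangular-lattice sites inside a disc.

    Hexagon centres form a triangular lattice with spacing ``pitch``;
    sites are at ``(i + j/2)·s, j·(√3/2)·s``. Counts every site whose
    centre lies within the disc (one lattice site per hexagon tile).
    """
    s = pitch
    count = 0
    jmax = int(disc_radius / (s * math.sqrt(3) / 2)) + 2
    for j in range(-jmax, jmax + 1):
        y = j * s * math.sqrt(3) / 2
        if abs(y) > disc_radius:
            continue
        half_chord = math.sqrt(disc_radius**2 - y**2)
        x_offset = j * s / 2
        i_lo = math.ceil((-half_chord - x_offset) / s)
        i_hi = math.floor((half_chord - x_offset) / s)
        count += max(0, i_hi - i_lo + 1)
    return count
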