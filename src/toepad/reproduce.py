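"""Recomputation of every published headline quantity.

Each check recomputes one printed number of the source study from the
package's models and compares it with the printed value at the precision
at which it was printed. :func:`run_all` returns the full table; the CLI
``toepad reproduce`` renders it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

from toepad import constants
from toepad.geometry import HexElementSpec, area_budget, default_geometry, projected_pad_area
from toepad.mechanics import capillary_length, drainage_crossover, hamaker_lower_bound
from toepad.measurements import IndentationTrial, tenacity_from_indentation
from toepad.sensitivity import critical_gap_vdw, predict_meniscus_curvature


@dataclass(frozen=True)
class Check:
    """One recomputed headline quantity."""

    name: str
    computed: float
    expected: float
    units: str
    rel_tol: float

    @property
    def passed(self) -> bool:
        return math.isclose(self.computed, self.expected, rel_tol=self.rel_tol)


def run_all() -> List[Check]:
    """Recompute all headline quantities from the default inputs."""
    geo = default_geometry()
    budget = area_budget(geo)
    checks = [
        Check(
            "projected_pad_area_mm2",
            projected_pad_area(3.6e-3) * 1e6,
            10.2,
            "mm2",
            0.01,
        ),
        Check("cell_count_thousands", budget.n_cells / 1e3, 126.0, "10^3", 0.01),
        Check("pillar_count_millions", budget.n_pillars / 1e6, 73.0, "10^6", 0.01),
        Check(
            "pillar_density_per_mm2_millions",
            budget.pillar_density * 1e-6 / 1e6,
            7.1,
            "10^6 mm^-2",
            0.02,
        ),
        Check("wetted_fold_cells", budget.wetted_fold_cells, 4.7, "fold", 0.01),
        Check("wetted_fold_total", budget.wetted_fold_total, 6.6, "fold", 0.01),
        Check("microchannel_fraction_pct", budget.frac_microchannel * 100, 20.0, "%", 0.02),
        Check("channel_fraction_pct", budget.frac_channels_total * 100, 58.0, "%", 0.01),
        Check("dimple_fraction_pct", budget.frac_dimple * 100, 32.0, "%", 0.02),
        Check("full_contact_fraction_pct", budget.frac_full_contact * 100, 10.0, "%", 0.06),
        Check(
            "capillary_length_mm",
            capillary_length(constants.GAMMA_MUCUS, constants.RHO_WATER, constants.G_STANDARD)
            * 1e3,
            2.7,
            "mm",
            0.01,
        ),
        Check(
            "drainage_crossover_um",
            drainage_crossover(HexElementSpec(10e-6, 10e-6, 1e-6)) * 1e6,
            1.0,
            "um",
            0.04,
        ),
        Check(
            "hamaker_lower_bound_zJ",
            hamaker_lower_bound(constants.T_LAB, constants.K_B) * 1e21,
            2.9,
            "1e-21 J",
            0.02,
        ),
        Check(
            "vdw_critical_gap_nm",
            critical_gap_vdw(1e3, 2.9e-21, 0.1) * 1e9,
            2.5,
            "nm",
            0.01,
        ),
        Check(
            "vdw_critical_gap_high_hamaker_nm",
            critical_gap_vdw(0.5e3, 2.9e-20, 0.1) * 1e9,
            6.7,
            "nm",
            0.01,
        ),
        Check(
            "indentation_tenacity_hi_mN_mm2",
            tenacity_from_indentation(IndentationTrial(609e-6, 1.5e-3, 50e-6)) * 1e-3,
            1.29,
            "mN mm^-2",
            0.01,
        ),
        Check(
            "indentation_tenacity_lo_mN_mm2",
            tenacity_from_indentation(IndentationTrial(585e-6, 1.5e-3, 350e-6)) * 1e-3,
            0.18,
            "mN mm^-2",
            0.02,
        ),
        Check(
            "predicted_meniscus_radius_um",
            predict_meniscus_curvature(0.17e3, 1.29e3, constants.GAMMA_MUCUS) * 1e6,
            150.0,
            "um",
            0.03,
        ),
    ]
    return checks


def format_table(checks: List[Check]) -> str:
    """Plain-text computed-vs-expected table."""
    lines = [f"{'quantity':38s} {'computed':>12s} {'expected':>10s} {'units':>12s}  status"]
    for c in checks:
        lines.append(
            f"{c.name:38s} {c.computed:12.4g} {c.expected:10.4g} {c.units:>12s}  "
            + ("ok" if c.passed else "FAIL")
        )
    return "\n".join(lines)
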