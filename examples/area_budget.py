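"""Area budget of the hierarchically patterned toe-pad surface.

Builds the reference pad (3.6 mm disc, 10 µm hexagonal epidermal cells,
300 nm nanopillars with 240 nm dimples) and prints how the pattern
multiplies the wetted surface and partitions the projected area.
"""

from toepad import area_budget, default_geometry

geometry = default_geometry()
budget = area_budget(geometry)

print(f"projected pad area   : {budget.projected_area * 1e6:.1f} mm^2")
print(f"epidermal cells      : {budget.n_cells / 1e3:.0f} x 10^3")
print(f"nanopillars          : {budget.n_pillars / 1e6:.0f} x 10^6 "
      f"({budget.pillars_per_cell} per cell)")
print(f"pillar density       : {budget.pillar_density * 1e-12:.1f} x 10^6 mm^-2")
print(f"wetted fold (cells)  : {budget.wetted_fold_cells:.1f}x")
print(f"wetted fold (total)  : {budget.wetted_fold_total:.1f}x")
print(f"channel fraction     : {budget.frac_channels_total:.0%} "
      f"(microchannels alone {budget.frac_microchannel:.0%})")
print(f"dimple fraction      : {budget.frac_dimple:.0%}")
print(f"full-contact fraction: {budget.frac_full_contact:.0%}")

# The folds say the channel walls make the liquid-accessible surface
# several times the pad's footprint; the fractions say only ~10% of the
# footprint can ever touch the substrate directly.
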