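# Reference toe-pad surface geometry of an adult hylid tree frog.
# Keys carry explicit unit suffixes; values are converted to SI on load.
pad_diameter_mm: 3.6
cell_diameter_um: 10
cell_height_um: 10
cell_channel_width_um: 1
pillar_diameter_nm: 300
pillar_height_nm: 300
pillar_channel_width_nm: 100
pillar_dimple_diameter_nm: 240
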