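# Device presets (all lengths in micrometres).
# cardiac_mps_v1: shallow barrier slot (h_b = 2 um, pore 8 um), 150 um deep
#   chamber/media channels; 8 pillars with 9 equal pores span the 708 um strip.
# cardiac_mps_v2: taller slot (h_b = 10 um, pore 10 um), 100 um deep channels.
cardiac_mps_v1:
  chamber_width_um: 300.0
  chamber_height_um: 150.0
  chamber_length_um: 708.0
  media_channel_width_um: 100.0
  media_channel_height_um: 150.0
  barrier:
    pore_size_um: 8.0
    pillar_diameter_um: 79.5
    n_pillars: 8
    pillar_height_um: 2.0
    strip_length_um: 708.0
    strip_depth_um: 125.0
cardiac_mps_v2:
  chamber_width_um: 300.0
  chamber_height_um: 100.0
  chamber_length_um: 708.0
  media_channel_width_um: 100.0
  media_channel_height_um: 100.0
  barrier:
    pore_size_um: 10.0
    pillar_diameter_um: 77.25
    n_pillars: 8
    pillar_height_um: 10.0
    strip_length_um: 708.0
    strip_depth_um: 125.0
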