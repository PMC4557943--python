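# End-to-end demo: 2 scotoma participants vs 2 controls, the study's
# 104 pedestrian appearances each (evenly split over city/highway drives
# and the four eccentricities).
seed: 11
simulate:
  n_cfl: 2
  n_nv: 2
  scenario:
    n_appearances: 104
  response:
    occ_slope: 0.3
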