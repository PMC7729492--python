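# Demo scenario: wild-type vs mutant-like (lipid-family and cortisol band
# amplitudes raised 30%), three mapped oocytes per group in classes III and IV.
name: demo
n_maps_per_group: 3
seed: 7
n_cytoplasm: 40
n_zona_radiata: 10

axis: {lo: 800.0, hi: 4000.0, step: 4.0}
pixel_um: 2.56
thickness_cv: 0.10
noise_sd: 0.002
vapor_amplitude: 0.03

classes:
  III:
    map_height_um: 328.0
    map_width_um: 328.0
    droplets: {n: 10, radius_um: [5.0, 10.0], lipid_boost: 4.0}
  IV:
    map_height_um: 164.0
    map_width_um: 492.0
    zr_thickness_um: 7.68

groups:
  wt:  {lipid_factor: 1.0, cortisol_factor: 1.0}
  gr:  {lipid_factor: 1.3, cortisol_factor: 1.3}
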