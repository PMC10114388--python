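bone_thickness_um: 40.0
cols: 5
contents_pct:
- 0.0
- 5.3
- 10.1
- 14.4
- 18.3
- 21.8
- 25.1
- 28.1
- 30.9
- 33.5
elastin_dims_um:
- 20.0
- 12.0
- 12.0
fibre_dims_um:
- 300.0
- 20.0
- 20.0
gap_um: 20.0
materials:
  bone:
    E_Pa: 17000000.0
    nu: 0.3
  collagen:
    E_Pa: 8900000.0
    nu: 0.48
  elastin:
    E_Pa: 4000000.0
    nu: 0.48
  sheet:
    E_Pa: 12700000.0
    nu: 0.48
rotation_deg: 30.0
rows: 3
shear_pa: 0.0009
sheet_dims_um:
- 300.0
- 62.0
- 128.0
sheet_reference_content_pct: 14.4
sheet_voxel_um:
- 4.0
- 3.875
- 4.0
slope_scalings:
- 1.0
- 2.0
tensile_pa: 0.15
voxel_um: 4.0
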