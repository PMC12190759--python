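n_samples_per_genotype: 3
n_lesions_per_sample: 30
lesion_size_mean_control: 16.8
lesion_size_mean_ko: 3.8
lesion_size_dispersion: 2.0
tumor_spread_sigma: 25.0
immune_ring_radius: 150.0
immune_per_lesion_mean: 80.0
n_background_cells: 2000
field_size:
- 5000.0
- 5000.0
min_lesion_separation: 600.0
niche_profiles:
  niche1:
    cd4_t: 0.22
    cd8_t: 0.22
    alveolar_macrophage: 0.16
    macrophage: 0.16
    cdc2: 0.14
    cd103_cdc: 0.02
    nk: 0.02
    nkt: 0.02
    mono_neutrophil: 0.04
  niche2:
    cd4_t: 0.03
    cd8_t: 0.03
    alveolar_macrophage: 0.04
    macrophage: 0.04
    cdc2: 0.02
    cd103_cdc: 0.24
    nk: 0.22
    nkt: 0.16
    mono_neutrophil: 0.22
niche_assignment_rule:
  control|dormant:
    niche1: 0.45
    niche2: 0.55
  control|proliferative:
    niche1: 0.95
    niche2: 0.05
  ko|dormant:
    niche1: 0.05
    niche2: 0.95
  ko|proliferative:
    niche1: 0.5
    niche2: 0.5
background_composition:
  cd4_t: 0.09045454545454545
  cd8_t: 0.09045454545454545
  nk: 0.09045454545454545
  nkt: 0.09045454545454545
  cd103_cdc: 0.09045454545454545
  cdc2: 0.09045454545454545
  alveolar_macrophage: 0.09045454545454545
  macrophage: 0.1809090909090909
  mono_neutrophil: 0.1809090909090909
  gd_t: 0.005
marker_panel:
  cell_types:
    tumor:
      gfp: +
      cd45: '-'
      cd3: '-'
      cd4: '-'
      cd8: '-'
      nk11: '-'
      cd11b: '-'
      cd11c: '-'
      cd103: '-'
      siglecf: '-'
      f480: '-'
      ly6g: '-'
      gdtcr: '-'
    cd4_t:
      gfp: '-'
      cd45: +
      cd3: +
      cd4: +
      cd8: '-'
      nk11: '-'
      cd11b: '-'
      cd11c: '-'
      cd103: '-'
      siglecf: '-'
      f480: '-'
      ly6g: '-'
      gdtcr: '-'
    cd8_t:
      gfp: '-'
      cd45: +
      cd3: +
      cd4: '-'
      cd8: +
      nk11: '-'
      cd11b: '-'
      cd11c: '-'
      cd103: '-'
      siglecf: '-'
      f480: '-'
      ly6g: '-'
      gdtcr: '-'
    gd_t:
      gfp: '-'
      cd45: +
      cd3: +
      cd4: '-'
      cd8: '-'
      nk11: '-'
      cd11b: '-'
      cd11c: '-'
      cd103: '-'
      siglecf: '-'
      f480: '-'
      ly6g: '-'
      gdtcr: +
    nk:
      gfp: '-'
      cd45: +
      cd3: '-'
      cd4: '-'
      cd8: '-'
      nk11: +
      cd11b: '-'
      cd11c: '-'
      cd103: '-'
      siglecf: '-'
      f480: '-'
      ly6g: '-'
      gdtcr: '-'
    nkt:
      gfp: '-'
      cd45: +
      cd3: +
      cd4: '-'
      cd8: '-'
      nk11: +
      cd11b: '-'
      cd11c: '-'
      cd103: '-'
      siglecf: '-'
      f480: '-'
      ly6g: '-'
      gdtcr: '-'
    cd103_cdc:
      gfp: '-'
      cd45: +
      cd3: '-'
      cd4: '-'
      cd8: '-'
      nk11: '-'
      cd11b: '-'
      cd11c: +
      cd103: +
      siglecf: '-'
      f480: '-'
      ly6g: '-'
      gdtcr: '-'
    cdc2:
      gfp: '-'
      cd45: +
      cd3: '-'
      cd4: '-'
      cd8: '-'
      nk11: '-'
      cd11b: +
      cd11c: +
      cd103: '-'
      siglecf: '-'
      f480: '-'
      ly6g: '-'
      gdtcr: '-'
    alveolar_macrophage:
      gfp: '-'
      cd45: +
      cd3: '-'
      cd4: '-'
      cd8: '-'
      nk11: '-'
      cd11b: '-'
      cd11c: +
      cd103: '-'
      siglecf: +
      f480: +
      ly6g: '-'
      gdtcr: '-'
    macrophage:
      gfp: '-'
      cd45: +
      cd3: '-'
      cd4: '-'
      cd8: '-'
      nk11: '-'
      cd11b: +
      cd11c: '-'
      cd103: '-'
      siglecf: '-'
      f480: +
      ly6g: '-'
      gdtcr: '-'
    mono_neutrophil:
      gfp: '-'
      cd45: +
      cd3: '-'
      cd4: '-'
      cd8: '-'
      nk11: '-'
      cd11b: +
      cd11c: '-'
      cd103: '-'
      siglecf: '-'
      f480: '-'
      ly6g: +
      gdtcr: '-'
  tumor_type_name: tumor
  exclusion_list:
  - gd_t
mfi_lognormal_params:
  gfp:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  cd45:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  cd3:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  cd4:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  cd8:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  nk11:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  cd11b:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  cd11c:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  cd103:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  siglecf:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  f480:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  ly6g:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
  gdtcr:
  - 6.214608098422191
  - 0.35
  - 2.995732273553991
  - 0.35
spillover: []
seed: 1
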