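cell_types:
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
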