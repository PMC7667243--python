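# Population template registry for the pidot-v1 panel.
#
# Terminal populations carry:
#   bands          marker -> band level (neg | lo | pos | hi), all 11 markers
#   scatter_mean   [FSC-A, SSC-A] in raw channel units
#   fraction_range [low, high] as fraction of total WBC events; a sample's
#                  true fraction is drawn uniformly inside this interval.
# Non-terminal nodes only anchor the hierarchy; their counts are sums of
# their terminal descendants.
#
# Fraction ranges are order-of-magnitude-plausible healthy-adult values
# (minor effector subsets sit below 1% of WBC); they are simulator inputs,
# not claims about any real cohort.
version: pidot-v1
populations:
  lymphocytes: {parent: null, terminal: false}
  b_cells: {parent: lymphocytes, terminal: false}
  pre_gc_b:
    parent: b_cells
    terminal: true
    fraction_range: [0.015, 0.030]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: neg, CD19: pos, CD16&CD56: neg, CD4: neg, CD8: neg,
            TCRgd: neg, CD27: neg, CD45RA: pos, IgM: pos, IgD: pos}
  unswitched_mbc_pc:
    parent: b_cells
    terminal: true
    fraction_range: [0.004, 0.008]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: neg, CD19: pos, CD16&CD56: neg, CD4: neg, CD8: neg,
            TCRgd: neg, CD27: pos, CD45RA: pos, IgM: pos, IgD: pos}
  switched_mbc_pc:
    parent: b_cells
    terminal: true
    fraction_range: [0.004, 0.008]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: neg, CD19: pos, CD16&CD56: neg, CD4: neg, CD8: neg,
            TCRgd: neg, CD27: lo, CD45RA: pos, IgM: neg, IgD: neg}
  igd_pos_igm_neg_post_gc:
    parent: b_cells
    terminal: true
    fraction_range: [0.0005, 0.0012]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: neg, CD19: pos, CD16&CD56: neg, CD4: neg, CD8: neg,
            TCRgd: neg, CD27: pos, CD45RA: pos, IgM: neg, IgD: pos}
  t_cells: {parent: lymphocytes, terminal: false}
  tcrgd_pos_t:
    parent: t_cells
    terminal: true
    fraction_range: [0.010, 0.020]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: neg, CD8: neg,
            TCRgd: pos, CD27: pos, CD45RA: pos, IgM: neg, IgD: neg}
  tcrgd_neg_dn_t:
    parent: t_cells
    terminal: true
    fraction_range: [0.003, 0.006]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: neg, CD8: neg,
            TCRgd: neg, CD27: pos, CD45RA: pos, IgM: neg, IgD: neg}
  cd4_t: {parent: t_cells, terminal: false}
  cd4_naive:
    parent: cd4_t
    terminal: true
    fraction_range: [0.060, 0.100]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: pos, CD8: neg,
            TCRgd: neg, CD27: pos, CD45RA: pos, IgM: neg, IgD: neg}
  cd4_cm:
    parent: cd4_t
    terminal: true
    fraction_range: [0.040, 0.060]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: pos, CD8: neg,
            TCRgd: neg, CD27: pos, CD45RA: neg, IgM: neg, IgD: neg}
  cd4_em:
    parent: cd4_t
    terminal: true
    fraction_range: [0.010, 0.020]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: pos, CD8: neg,
            TCRgd: neg, CD27: neg, CD45RA: neg, IgM: neg, IgD: neg}
  cd4_td:
    parent: cd4_t
    terminal: true
    fraction_range: [0.002, 0.005]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: pos, CD8: neg,
            TCRgd: neg, CD27: neg, CD45RA: pos, IgM: neg, IgD: neg}
  cd8_t: {parent: t_cells, terminal: false}
  cd8_naive:
    parent: cd8_t
    terminal: true
    fraction_range: [0.030, 0.050]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: neg, CD8: pos,
            TCRgd: neg, CD27: pos, CD45RA: pos, IgM: neg, IgD: neg}
  cd8_cm:
    parent: cd8_t
    terminal: true
    fraction_range: [0.010, 0.020]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: neg, CD8: pos,
            TCRgd: neg, CD27: pos, CD45RA: neg, IgM: neg, IgD: neg}
  cd8_em:
    parent: cd8_t
    terminal: true
    fraction_range: [0.004, 0.008]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: neg, CD8: pos,
            TCRgd: neg, CD27: neg, CD45RA: neg, IgM: neg, IgD: neg}
  cd8_td27pos:
    parent: cd8_t
    terminal: true
    fraction_range: [0.002, 0.004]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: neg, CD8: pos,
            TCRgd: neg, CD27: lo, CD45RA: pos, IgM: neg, IgD: neg}
  cd8_td27neg:
    parent: cd8_t
    terminal: true
    fraction_range: [0.003, 0.006]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: neg, CD8: pos,
            TCRgd: neg, CD27: neg, CD45RA: pos, IgM: neg, IgD: neg}
  cd4_cd8_dp_t:
    parent: t_cells
    terminal: true
    fraction_range: [0.001, 0.002]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: pos, CD19: neg, CD16&CD56: neg, CD4: pos, CD8: pos,
            TCRgd: neg, CD27: pos, CD45RA: pos, IgM: neg, IgD: neg}
  nk_cells:
    parent: lymphocytes
    terminal: true
    fraction_range: [0.020, 0.040]
    scatter_mean: [55000, 12000]
    bands: {CD45: hi, CD3: neg, CD19: neg, CD16&CD56: hi, CD4: neg, CD8: neg,
            TCRgd: neg, CD27: neg, CD45RA: lo, IgM: neg, IgD: neg}
nuisance:
  debris:
    scatter_mean: [6000, 3000]
    scatter_sd: [2500, 1500]
    bands: {CD45: neg, CD3: neg, CD19: neg, CD16&CD56: neg, CD4: neg, CD8: neg,
            TCRgd: neg, CD27: neg, CD45RA: neg, IgM: neg, IgD: neg}
  other_leukocyte:
    scatter_mean: [120000, 65000]
    scatter_sd: [12000, 9000]
    bands: {CD45: pos, CD3: neg, CD19: neg, CD16&CD56: neg, CD4: lo, CD8: neg,
            TCRgd: neg, CD27: neg, CD45RA: lo, IgM: neg, IgD: neg}
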