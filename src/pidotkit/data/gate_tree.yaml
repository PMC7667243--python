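# Boolean manual-gating hierarchy for the pidot-v1 panel.
#
# Each node lists its parent and the marker-band requirements an event must
# satisfy *in addition to* the requirements already applied on the path from
# the root.  Band tokens:
#   "-"      negative band only
#   "lo"     low band only
#   "+"      positive or high band
#   "hi"     high band only
#   "-..lo"  negative or low
#   "lo..+"  low, positive or high
#   "-..+"   negative, low or positive (not high)
# The root (lymphocytes) is applied by the scatter/CD45 lymphocyte gate;
# events matching no sibling at a level fall into that parent's
# "unclassified" remainder bucket.
version: pidot-v1
nodes:
  lymphocytes: {parent: null, terminal: false, requires: {}}
  b_cells:
    parent: lymphocytes
    terminal: false
    requires: {CD45: hi, CD19: "+", CD3: "-", CD45RA: "+"}
  t_cells:
    parent: lymphocytes
    terminal: false
    requires: {CD45: hi, CD3: "+", CD19: "-", CD16&CD56: "-..lo"}
  nk_cells:
    parent: lymphocytes
    terminal: true
    requires: {CD45: hi, CD19: "-", CD3: "-", CD16&CD56: hi, CD45RA: "lo..+"}
  pre_gc_b:
    parent: b_cells
    terminal: true
    requires: {CD27: "-", IgD: "+", IgM: "+"}
  unswitched_mbc_pc:
    parent: b_cells
    terminal: true
    requires: {IgD: "+", IgM: "+", CD27: "+"}
  switched_mbc_pc:
    parent: b_cells
    terminal: true
    requires: {IgD: "-", IgM: "-", CD27: "-..+"}
  igd_pos_igm_neg_post_gc:
    parent: b_cells
    terminal: true
    requires: {IgD: "+", IgM: "-", CD27: "+"}
  tcrgd_pos_t:
    parent: t_cells
    terminal: true
    requires: {TCRgd: "+", CD4: "-", CD8: "-..lo"}
  tcrgd_neg_dn_t:
    parent: t_cells
    terminal: true
    requires: {TCRgd: "-", CD4: "-", CD8: "-..lo"}
  cd4_t:
    parent: t_cells
    terminal: false
    requires: {TCRgd: "-", CD4: "+", CD8: "-"}
  cd8_t:
    parent: t_cells
    terminal: false
    requires: {TCRgd: "-", CD4: "-", CD8: "+"}
  cd4_cd8_dp_t:
    parent: t_cells
    terminal: true
    requires: {TCRgd: "-", CD4: "+", CD8: "+"}
  cd4_naive: {parent: cd4_t, terminal: true, requires: {CD27: "+", CD45RA: "+"}}
  cd4_cm:    {parent: cd4_t, terminal: true, requires: {CD27: "+", CD45RA: "-"}}
  cd4_em:    {parent: cd4_t, terminal: true, requires: {CD27: "-", CD45RA: "-"}}
  cd4_td:    {parent: cd4_t, terminal: true, requires: {CD27: "-", CD45RA: "+"}}
  cd8_naive: {parent: cd8_t, terminal: true, requires: {CD27: "+", CD45RA: "+"}}
  cd8_cm:    {parent: cd8_t, terminal: true, requires: {CD27: "+", CD45RA: "-"}}
  cd8_em:    {parent: cd8_t, terminal: true, requires: {CD27: "-", CD45RA: "-"}}
  cd8_td27pos: {parent: cd8_t, terminal: true, requires: {CD27: lo, CD45RA: "+"}}
  cd8_td27neg: {parent: cd8_t, terminal: true, requires: {CD27: "-", CD45RA: "+"}}
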