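# Alternate channel labels (as found in FCS files from other acquisition
# setups) mapped to the canonical short names of the pidot-v1 panel.
# Keys are matched case-insensitively; edit or extend freely.
"fsc-a": FSC-A
"fsc-area": FSC-A
"fsc-h": FSC-H
"fsc-height": FSC-H
"ssc-a": SSC-A
"ssc-area": SSC-A
"cd56 cd16": CD16&CD56
"cd16 cd56": CD16&CD56
"cd16+cd56": CD16&CD56
"cd16/cd56": CD16&CD56
"cd16&cd56": CD16&CD56
"tcrgd": TCRgd
"tcr gd": TCRgd
"tcr gamma delta": TCRgd
"tcr-gd": TCRgd
"anti-tcrgd": TCRgd
"igm": IgM
"igd": IgD
"cd45ra": CD45RA
"cd45": CD45
"cd3": CD3
"cd4": CD4
"cd8": CD8
"cd19": CD19
"cd27": CD27
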