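# Published headline constants of the two canine capture designs and the
# cohort they were validated on.  These are inputs for consistency checks
# and percentage recomputation; the summary module never quotes averages
# from here — those are always recomputed from the per-sample tables.
designs:
  exome_plus:
    total_bp: 151698592
    n_regions: 242914
  exome_cds:
    total_bp: 71254801
    n_regions: 244543
    transdecoder_only_bp: 115044   # CDS bases not shared with exome-plus
  exome_1_0:
    total_bp: 52000000             # approximate (quoted as ~52 Mb)
    mean_region_bp: 260

reproducibility:
  n_samples: 16
  regions_fully_covered_all: 154318
  regions_never_all: 4220
  bp_covered_all: 137071014
  bp_never_all: 3642390

groups:
  group1_n: 154318
  group2_n: 84376
  group3_n: 4220
  gc_cutoff_lo: 32.0
  gc_cutoff_hi: 64.5

# Venn membership classes between exome-1.0 (A), exome-CDS (B) and
# exome-plus (C), in Mb as printed on the comparison figure.
venn_mb:
  only_exome_1_0: 0.09
  only_exome_cds: 0.12
  only_exome_plus: 62.99
  exome_1_0_and_cds_only: 0.0
  exome_1_0_and_plus_only: 17.57
  exome_cds_and_plus_only: 36.37
  all_three: 34.77
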