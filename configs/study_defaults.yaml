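# The study-parameter preset: every pipeline tunable under its documented
# default.  Point the `inputs` block at your own data (paths are resolved
# relative to this file) and run `methylgraft run --config <this> --out <dir>`.
inputs:
  reference_calls: [calls_OG_rep1.tsv, calls_OG_rep2.tsv, calls_OG_rep3.tsv]
  test_calls: [calls_SD_rep1.tsv, calls_SD_rep2.tsv, calls_SD_rep3.tsv]
  features: features.gff3
  det_table: det.tsv
  bin_map: bin_map.tsv
  chrom_lengths: chroms.tsv
conditions:
  reference: OG
  test: SD
dmr:
  window_size: 200       # bp sliding windows
  step: 100              # bp overlap steps
  min_site_coverage: 3   # reads per cytosine (3x)
  min_sites_per_window: 4
  p_threshold: 0.01      # raw per-window p <= 1%
  sda_threshold: {CG: 10, CHG: 10, CHH: 5}   # reproducibility ceilings, pp
  min_abs_delta: 0
  stat: student          # student | welch | fisher
association:
  flank: 2000            # bp, promoter/terminator width and linking distance
dets:
  alpha: 0.01            # DET selection p <= 1%
integration:
  contexts: [CHH]
  min_abs_ratio: 1.5     # |log2 ratio| threshold
density:
  bin_size: 50000        # bp bins for the DMR density track
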