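# Default run parameters. These are declared operating points, not measured
# instrument constants; override any of them via a user config file or CLI flags.
channels:
  - {channel_id: 1, motif: GCTCTTC, display_name: Nt.BspQI}
  - {channel_id: 2, motif: CCTCAGC, display_name: Nt.BbvCI}

simulation:
  coverage_per_clone: 100
  label_efficiency: 0.85
  false_label_rate: 1.0        # expected false labels per 100 kb per channel
  sizing_sd_bp: 300.0
  optical_resolution_bp: 1000.0
  stretch_mean: 0.85           # fraction of B-DNA contour length in the channel
  stretch_sd: 0.02
  flip_probability: 0.5
  seed: 0

consensus:
  bin_width_bp: 800.0          # rasterization bin for pairwise molecule distance
  hist_bin_bp: 500.0           # label histogram bin for peak calling
  resolution_bp: 1000.0        # same-channel peaks closer than this are merged
  support_threshold: 0.3       # fraction of molecules required under a peak
  max_peak_sd_bp: 650.0        # wider candidate peaks are rejected as non-discrete
  min_support: 5               # smallest usable cluster
  cut_height: null             # null -> 0.6 x median pairwise distance
  linkage: average

alignment:
  match_bonus: 5.0
  miss_penalty: 3.0            # unmatched reference label inside the aligned span
  false_penalty: 3.0           # unmatched query label inside the aligned span
  sd_scale: 0.05               # interval variance grows linearly with its length
  sd_base_bp: 150.0
  penalty_cap: 25.0            # cap on a single interval penalty (outlier intervals)
  min_score: 10.0
  min_labels: 5
  max_skip: 8                  # DP lookback window, in labels

asmcheck:
  tol_bp: null                 # null -> max(1500, 3 x pooled interval sd)
  min_gap_labels: 3
  merge_bridge_bp: 6000.0      # same-kind events bridged by shorter clean spans merge
  condense_bp: 1000.0          # condense in-silico query labels to optical resolution
  window_bp: 3000.0            # sliding window for label-density screening
  repeat_bin_bp: 500.0
  density_threshold: 1.5
  min_mol_count: 1.0

seed: 0
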