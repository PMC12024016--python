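# Full-pipeline configuration: `lbstock report examples/config.yaml`
# (generate the inputs first with `lbstock simulate --out-prefix demo`)
seed: 1
inputs:
  length_frequency: demo_lf.csv     # year,bin_lower_mm,count
  length_weight: demo_lw.csv        # length_mm,weight_g[,sex][,year]
  logbook: demo_logbook.csv         # date,lat,lon,nets,catch_t
mean_temp_c: 25.0                   # scalar, or a {year: temp} mapping
elefan:
  linf_range: [34, 46]              # cm
  k_range: [0.3, 1.0]               # 1/yr
  grid: [40, 30]
lbb:
  use_elefan_linf: true             # centre the Linf prior on the ELEFAN fit
  mcmc: {chains: 3, iterations: 20000, burn_in: 5000}
  # priors:                         # optional per-year overrides, e.g.
  #   2016: {linf_prior: 41.2, lc_prior: 19.4, mk_prior: 1.5, fk_prior: 0.78}
output_dir: out
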