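# Default study configuration mirroring the shape of the source field study:
# 26 collection sites, 2-5 specimens per site, five barcode markers, ABGD-
# style delimitation sweep over P in [0.001, 0.100] with X = 1.5, Fst
# significance from 1023 permutations, a 25% SDM test split, and outlier
# screening at a minimum of 3 of 19 bioclimatic variables.
simulate:
  n_sites: 26
  specimens_per_site: [2, 5]
  k_species: 4
  intra: 0.005
  inter: 0.08
  kappa: 2.0
  markers:
    rbcL: 600
    matK: 800
    trnH-psbA: 450
    ITS2: 350
    ycf: 500
  hit_table:
    score_noise_sd: 0.5
    decoy_rate: 0.1
  landscape:
    n_vars: 19
    nrows: 40
    ncols: 40
    dominant_coeff: 4.0
    n_presence: 120
distance:
  model: K2P
delimit:
  P_min: 0.001
  P_max: 0.100
  n_steps: 10
  X: 1.5
  W: 10
  report_prior: 0.01
assign:
  methods: [simple, optimized]
  deviation: 0.01
popgen:
  n_perm: 1023
sdm:
  test_fraction: 0.25
  beta: 1.0
  n_background: 10000
  min_flagged_vars: 3
  jackknife: true
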