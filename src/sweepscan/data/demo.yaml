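# Demo run: four-breed synthetic panel with one planted sweep and one
# planted autozygosity tract.  Analysis parameters are the package
# defaults: 40 kb windows / 20 kb step, 3% right tail, MAF > 0.05,
# call rate > 0.9, PLINK-style ROH rules, haplotype count > 2.
seed: 1

simulate:
  n_breeds: 4
  samples_per_breed: [8, 8, 8, 8]
  breed_names: [JL, EHL, LW, WB]
  breed_groups: {JL: TEB, EHL: black, LW: white, WB: wild}
  n_chromosomes: 1
  chrom_length: 2000000
  snp_density: 0.001
  drift_F: 0.05
  missing_rate: 0.02
  sweep:
    chrom: "1"
    start: 900000
    end: 940000
    swept_breeds: [JL]
  roh:
    - [EHL_s1, "1", 400000, 1600000]

filter:
  maf_min: 0.05
  call_rate_min: 0.9

scan:
  pop_a: JL
  pop_b: WB
  window_bp: 40000
  step_bp: 20000
  tail: 0.03
  lsbl: {a: JL, b: EHL, c: LW}

haplo:
  min_count: 2
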