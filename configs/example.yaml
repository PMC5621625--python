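# Toy end-to-end run on synthetic inputs.
seed: 1
outdir: runs/example
outcomes: [wasted]

mcmc:
  chains: 2
  iterations: 1200
  burnin: 500
  thinning: 2

sim:
  n_districts: 6
  clusters_per_district: 5
  n_children: 2000
  n_rounds: 4
  start_date: "2007-01-01"
  end_date: "2010-12-31"

af:
  factors: [recent, longer, evi]
  scaling: none
  evi_reference_quantile: 0.9
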