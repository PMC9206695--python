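# Packaged demo: synthetic fermentation with 5 planted producer genera
# among 50, 6 timepoints x 3 replicates, 10% multiplicative noise.
outdir: results/demo
seed: 42
sim:
  n_taxa: 50
  n_timepoints: 6
  n_replicates: 3
  n_producers: 5
  n_has: 10
  effect_size: 1.0
  noise_sd: 0.1
  dominant_taxon_fraction: 0.5
  detection_limit: 0.0
o2pls:
  # joint rank: one component per driven HA (5 planted) plus headroom for
  # compositional nuisance directions; the permutation null calibrates
  # the extra components
  n: 7
  nx: 1
  ny: 1
  n_perm: 1000
  alpha: 0.05
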