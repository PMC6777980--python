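# Default parameters of the paired tracer/tractography simulator.
# All tunables live here; the code never hard-codes them.
synthetic:
  n_regions: 8          # visual-cortical parcellation scale
  edge_density: 0.75    # probability an ordered pair is connected
  reciprocity: 0.7      # probability a connection's reciprocal is forced
  mu: 0.0               # log-mean of lognormal connection weights
  sigma: 1.5            # log-sd of lognormal connection weights
  lambda_decay: 0.2     # per-mm exponential decay of true weights
  box_size: 20.0        # mm; centroids drawn uniformly in this cube
  tracer_neurons: 10000     # labeled neurons per injection (M)
  streamlines: 1000000      # total streamlines tracked (T)
  gamma: 0.1            # per-mm distance-dependent streamline dropout
  epsilon: 0.01         # false-positive floor, relative to mean weight
  allocation: multinomial   # or: poisson
analysis:
  n_boot: 10000
  ci_level: 0.95
  removal_step: 0.05
  removal_max: 0.5
  densities: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
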