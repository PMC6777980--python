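{
 "associations": {
  "partial_spearman/directed": {
   "ci_high": null,
   "ci_low": null,
   "coefficient": 0.5907133276144735,
   "n_edges": 56,
   "p": 1.6467307483239952e-06
  },
  "partial_spearman/symmetric": {
   "ci_high": null,
   "ci_low": null,
   "coefficient": 0.7301587301587301,
   "n_edges": 28,
   "p": 1.0319798577326957e-05
  },
  "pearson_log/directed": {
   "ci_high": 0.8255978187755569,
   "ci_low": 0.6049056152768792,
   "coefficient": 0.7351409346989501,
   "n_edges": 56,
   "p": 1.1077229472898291e-10
  },
  "pearson_log/symmetric": {
   "ci_high": 0.9088944652809955,
   "ci_low": 0.701449097880466,
   "coefficient": 0.8258767439970865,
   "n_edges": 28,
   "p": 6.261227747345365e-08
  },
  "spearman/directed": {
   "ci_high": 0.8585552999941932,
   "ci_low": 0.5475901806014525,
   "coefficient": 0.7355662338453591,
   "n_edges": 56,
   "p": 1.067149096728089e-10
  },
  "spearman/symmetric": {
   "ci_high": 0.9475454304689728,
   "ci_low": 0.612791497788601,
   "coefficient": 0.8248494800218937,
   "n_edges": 28,
   "p": 6.717078950477049e-08
  }
 },
 "detection": {
  "matched/0.1": [
   1.0,
   1.0,
   1.0
  ],
  "matched/0.2": [
   0.8333333333333334,
   0.9545454545454546,
   0.8333333333333334
  ],
  "matched/0.3": [
   1.0,
   1.0,
   1.0
  ],
  "matched/0.4": [
   0.8333333333333334,
   0.875,
   0.8333333333333334
  ],
  "matched/0.5": [
   0.7857142857142857,
   0.7857142857142857,
   0.7857142857142857
  ],
  "matched/0.6": [
   0.7647058823529411,
   0.6363636363636364,
   0.7647058823529411
  ],
  "matched/0.7": [
   0.8,
   0.5,
   0.8
  ],
  "matched/0.8": [
   0.9130434782608695,
   0.6,
   0.9130434782608695
  ],
  "matched/0.9": [
   0.9230769230769231,
   0.0,
   0.9230769230769231
  ],
  "sweep/0.1": [
   0.9642857142857143,
   0.5357142857142857,
   0.3314826113178251
  ],
  "sweep/0.2": [
   0.9047619047619049,
   0.5876623376623379,
   0.5248699845404122
  ],
  "sweep/0.3": [
   0.8571428571428571,
   0.642857142857143,
   0.6744223237493937
  ],
  "sweep/0.4": [
   0.7619047619047618,
   0.6651785714285714,
   0.744505673332099
  ],
  "sweep/0.5": [
   0.7142857142857143,
   0.6785714285714286,
   0.7906157559348721
  ],
  "sweep/0.6": [
   0.6659663865546219,
   0.711038961038961,
   0.8554462089043868
  ],
  "sweep/0.7": [
   0.6124999999999999,
   0.71875,
   0.8989099787676794
  ],
  "sweep/0.8": [
   0.5854037267080745,
   0.792857142857143,
   0.9557791615647894
  ],
  "sweep/0.9": [
   0.5357142857142858,
   0.7142857142857143,
   0.9750837533232056
  ]
 },
 "removal": {
  "directed/strongest/0.0": 0.7355662338453591,
  "directed/strongest/0.25": 0.5298817203192537,
  "directed/strongest/0.5": 0.29898620320416824,
  "directed/weakest/0.0": 0.7355662338453591,
  "directed/weakest/0.25": 0.7078047495105377,
  "directed/weakest/0.5": 0.6691332665878498,
  "symmetric/strongest/0.0": 0.8248494800218937,
  "symmetric/strongest/0.25": 0.5883116883116883,
  "symmetric/strongest/0.5": 0.3758241758241759,
  "symmetric/weakest/0.0": 0.8248494800218937,
  "symmetric/weakest/0.25": 0.8415584415584414,
  "symmetric/weakest/0.5": 0.9472527472527472
 }
}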