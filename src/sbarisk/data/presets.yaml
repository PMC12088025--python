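# Built-in cohort presets: published summary statistics of the source
# cohorts behind the risk model's two input distributions, together
# with the settings used to calibrate truncated-normal-mixture
# surrogates for the (unavailable) raw data.
#
# kind: onset  -> labour-onset offset ADD - EDD, days relative to EDD
# kind: latent -> latent-phase duration, hours, by parity
#
# shape_points are published risk-table values re-expressed as CDF
# points (for latent presets, G(t) = 1 - P(SBA) in the no-MWH column);
# they softly resolve mixture-shape freedom left over after the hard
# mean/SD/percentile constraints and are not themselves constraints.
# kde_support is the value range used when fitting a KDE to samples
# from this cohort; default_n is the published cohort size.

khambalia:
  kind: onset
  mean: -1.48          # days
  sd: 9.21             # days
  interval_mass: {lo: -7.0, hi: 7.0, mass: 0.66}
  support: [-30.0, 30.0]
  kde_support: [-30.0, 30.0]
  n_components: 2
  default_n: 10243

mongelli:
  kind: onset
  mean: -1.79          # days
  sd: 11.3             # days
  support: [-30.0, 30.0]
  kde_support: [-30.0, 30.0]
  n_components: 1
  default_n: 34249

friedman_nulliparous:
  kind: latent
  parity: nulliparous
  mean: 7.1            # hours
  sd: 4.0              # hours
  quantile: {level: 0.95, value: 20.0}
  support: [0.0, 30.0]
  kde_support: [0.0, 30.0]
  n_components: 2
  default_n: 500
  shape_points:
    - [1.0, 0.04]
    - [2.0, 0.08]
    - [3.0, 0.14]
    - [3.5, 0.18]
    - [4.0, 0.22]
    - [4.5, 0.26]
    - [5.0, 0.30]
    - [5.5, 0.34]
    - [6.0, 0.38]
    - [6.5, 0.42]
    - [7.0, 0.46]
    - [7.5, 0.50]
    - [8.0, 0.54]
    - [8.5, 0.58]
    - [9.0, 0.61]
    - [9.5, 0.64]
    - [10.0, 0.67]
    - [10.5, 0.70]
    - [11.0, 0.72]
    - [11.5, 0.74]
    - [12.0, 0.76]
    - [12.5, 0.78]

friedman_multiparous:
  kind: latent
  parity: multiparous
  mean: 5.3            # hours
  sd: 4.1              # hours
  quantile: {level: 0.95, value: 14.0}
  support: [0.0, 30.0]
  kde_support: [0.0, 16.0]
  n_components: 2
  default_n: 500
  shape_points:
    - [1.0, 0.07]
    - [2.0, 0.18]
    - [3.0, 0.31]
    - [3.5, 0.38]
    - [4.0, 0.44]
    - [4.5, 0.50]
    - [5.0, 0.56]
    - [5.5, 0.61]
    - [6.0, 0.65]
    - [6.5, 0.70]
    - [7.0, 0.74]
    - [7.5, 0.77]
    - [8.0, 0.81]
    - [8.5, 0.84]
    - [9.0, 0.86]
    - [9.5, 0.88]
    - [10.0, 0.90]
    - [10.5, 0.92]
    - [11.0, 0.94]
    - [11.5, 0.95]
    - [12.0, 0.96]
    - [12.5, 0.97]
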