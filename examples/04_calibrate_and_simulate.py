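"""Calibrate a surrogate mixture and draw a synthetic cohort from it.

The source cohorts are published only as summary statistics; a
truncated normal mixture matched to them (here: the multiparous
latent-phase cohort — mean 5.3 h, SD 4.1 h, 95th percentile 14 h)
stands in for the raw data and powers the seeded cohort generator.
"""

import numpy as np

import sbarisk as sk

spec = sk.CalibrationSpec(
    target_mean=5.3,
    target_sd=4.1,
    support=(0.0, 30.0),
    n_components=2,
    target_quantile=(0.95, 14.0),
)
mix = sk.calibrate_mixture(spec)
mean, sd, _, q = sk.mixture_moments(mix, quantile_levels=[0.95])
print(f"calibrated mixture: weights {np.round(mix.weights, 4)}")
print(f"  component means {np.round(mix.means, 3)} h, SDs {np.round(mix.sds, 3)} h")
print(f"  verified by quadrature: mean {mean:.4f} h, SD {sd:.4f} h, P95 {q[0]:.4f} h")

draws = sk.sample_cohort("friedman_multiparous", n=100_000, seed=1)
print(f"\n100,000 seeded draws: mean {draws.mean():.3f} h, SD {draws.std(ddof=1):.3f} h,"
      f" P95 {np.percentile(draws, 95):.2f} h")
print("(sample statistics reproduce the published cohort statistics within Monte-Carlo error)")

report = sk.end_to_end_recovery(n_onset=10_243, n_latent=500, seed=1)
print(f"\nend-to-end recovery at the published cohort sizes: "
      f"max table-cell deviation {report.worst:.3f}")
print("(sampling + KDE + table pipeline, compared against the exact surrogate tables)")
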