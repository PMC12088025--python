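"""Bootstrap 95% confidence intervals for risk-table cells.

Both input datasets are resampled with replacement at their original
sizes, the CDFs re-estimated by the same truncated Gaussian KDE, and
every cell recomputed; the 2.5th/97.5th percentiles of the replicates
give the interval.  The running SD of the replicated values monitors
convergence.
"""

import sbarisk as sk

onset = sk.sample_cohort("khambalia", 10_243, seed=1)       # synthetic stand-in cohorts
latent = sk.sample_cohort("friedman_multiparous", 500, seed=2)

grid = [sk.AccessTimeInterval(5.0, 5.5), sk.AccessTimeInterval(10.0, 10.5)]
config = sk.BootstrapConfig(max_iterations=1000, convergence_window=100, seed=0)
cis = sk.bootstrap_cis(
    onset,
    {"multiparous": latent},
    grid=grid,
    move_dates=sk.DEFAULT_MOVE_DATES,
    latent_supports={"multiparous": (0.0, 30.0)},
    config=config,
)["multiparous"]

F = sk.kde_estimate(onset, 0.3, (-30.0, 30.0))
G = sk.kde_estimate(latent, 0.3, (0.0, 30.0), parity="multiparous")
labels = ["no MWH", "on EDD", "-7 d", "-14 d", "-21 d", "-28 d"]
for i, iv in enumerate(grid):
    print(f"access time {iv.label} h:")
    for j, lab in enumerate(labels):
        ci = cis[(i, j)]
        point = sk.cell_value(iv, sk.DEFAULT_MOVE_DATES[j], "multiparous", F, G).p_sba
        print(f"  {lab:>7}: {point:.2f} [{ci.lower:.2f}, {ci.upper:.2f}]"
              f"  ({ci.n_iterations_used} replicates, converged={ci.converged})")
print("\nintervals quantify sampling error of the cohort-based CDF estimates;")
print("the latent cohort (n=500) dominates the width of the no-MWH column")
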