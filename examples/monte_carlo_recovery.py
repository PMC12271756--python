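"""Parameter-recovery experiment under correct and misspecified effect priors.

Runs a small slice of the Monte Carlo validation grid: effects drawn with
AR(1) autocorrelation rho in {0, 0.8} at true h2 = 0.2 on a
block-correlated design.  At rho = 0 the model is correctly specified and
posterior intervals should cover the generating values; at rho = 0.8 the
independence assumption of the effect prior is violated and h2 is biased
upward.
"""

from brainvc import McmcConfig, PriorSpec, SimulationConfig, run_grid_experiment

base = SimulationConfig(
    n=300, B=1500, M=10,
    alpha_true=(-1.13, 0.38) + (0.0,) * 8,
    annotation_fractions=(0.09,) * 10,
    x_model="block", block_size=50, block_rho=0.5,
)
table = run_grid_experiment(
    rhos=(0.0, 0.8),
    h2s=(0.2,),
    base_config=base,
    prior=PriorSpec(sigma_alpha_sq=4.0),
    mcmc=McmcConfig(n_iterations=2000, n_burnin=800, thin=5, n_chains=2),
    seed=3,
)
cols = ["rho", "h2_true", "h2_mean", "h2_lo", "h2_hi",
        "alpha_1_mean", "alpha_2_mean", "beta_coverage", "r2_median"]
print(table[cols].round(3).to_string(index=False))
print("\nAt rho=0 the h2 interval covers the generating value; at rho=0.8 "
      "the posterior mean of h2 far exceeds the generating value 0.2 — the "
      "documented upward bias under serially correlated effects. (At this "
      "reduced n the per-feature beta coverage runs a few points below "
      "nominal; the full-scale validation in scripts/acceptance.py uses "
      "n=600, B=3000.)")
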