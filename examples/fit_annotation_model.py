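"""Fit the annotation-informed variance-components model to simulated data.

Generates a cohort where features carrying a single binary annotation are
enriched (each annotated feature explains exp(0.5) ~ 1.65x as much variance
as an unannotated one), fits the model by MCMC, and prints the posterior
summary: the total fraction of variance explained h2, the annotation
weight alpha with its enrichment ratio exp(alpha), and whether the 95%
credible interval excludes zero.
"""

import numpy as np

from brainvc import (
    McmcConfig,
    PriorSpec,
    SimulationConfig,
    run_mcmc,
    simulate_dataset,
    summarize,
)

sim = simulate_dataset(
    SimulationConfig(
        n=400, B=1200, M=1, h2_true=0.4, alpha_true=(0.5,),
        annotation_fractions=(0.15,), x_model="block", seed=7,
    )
)
draws = run_mcmc(
    sim.data,
    PriorSpec(sigma_alpha_sq=4.0),
    McmcConfig(n_iterations=2500, n_burnin=1000, thin=5, n_chains=3, seed=1),
)
summary = summarize(draws, annotation_names=["Enriched-Enriched"])

h2 = summary["h2"]
a = summary["Enriched-Enriched"]
print(f"true h2 = {sim.config.h2_true}, true alpha = 0.5")
print(f"h2 posterior median (95% CI): "
      f"{h2['median']:.2f} ({h2['lo']:.2f}, {h2['hi']:.2f})")
print(f"alpha posterior median (95% CI): "
      f"{a['median']:.2f} ({a['lo']:.2f}, {a['hi']:.2f})  flag: {a['flag']}")
print(f"enrichment exp(alpha): {a['enrichment']:.2f} "
      f"({a['enrichment_lo']:.2f}, {a['enrichment_hi']:.2f})")
print("Interpretation: h2 is the share of phenotype variance explained by "
      "all features jointly; exp(alpha) > 1 means annotated features carry "
      "more variance per feature.")
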