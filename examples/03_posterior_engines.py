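"""The three posterior engines side by side on one problem.

Fits the same third-order polynomial network to the same noisy cubic data
with the Laplace approximation, NUTS sampling, and mean-field variational
inference, then prints the x^3 coefficient posterior from each.  Also runs
the Geweke convergence diagnostic on the NUTS chain.  Takes ~2 minutes
(NUTS dominates).
"""

import numpy as np

from pinets.benchmarks import experiment_spec, generate_dataset
from pinets.mcmc import HMCSettings, geweke_coefficients
from pinets.pipeline import fit_cubic_pipeline
from pinets.vi import VISettings

ds = generate_dataset(experiment_spec("cubic", seed=989))
x = ds.replicates[0].times
y = ds.replicates[0].states[:, 0]

rows = {}
rows["laplace"] = fit_cubic_pipeline("laplace", x, y, seed=989)
nuts = fit_cubic_pipeline("nuts", x, y, seed=989, full_result=True,
                          mcmc_settings=HMCSettings(warmup=1000, samples=1000,
                                                    max_tree_depth=8))
rows["nuts"] = nuts.coeff_samples
rows["vi"] = fit_cubic_pipeline("vi", x, y, seed=989,
                                vi_settings=VISettings(iterations=12000,
                                                       grad_samples=8,
                                                       learning_rate=0.01,
                                                       seed=989))

print("x^3 coefficient (truth 4):")
for name, cs in rows.items():
    col = cs.column((3,))
    print(f"  {name:8s} {col.mean():6.3f} +- {col.std():5.3f}")

g, labels = geweke_coefficients(nuts.chain, nuts.config)
print("\nNUTS Geweke statistics per expanded coefficient (|T| <= 1.964 passes):")
for lab, t in zip(labels, g.T):
    print(f"  {lab:4s} T = {t:+.3f}")

print("\nExpect: the three engines agree on the coefficient's location, and a")
print("converged chain keeps every |T| under the 0.05-level critical value.")
print("Mean-field VI is overconfident in the *parameter* basis (its marginal")
print("variances provably undershoot on correlated targets), but pushing the")
print("factorized posterior through the polynomial expansion breaks the")
print("weight-bias correlations, so the expanded-coefficient spread need not")
print("come out narrower than the Laplace one.")
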