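"""Equation discovery for a noisy predator-prey system.

Simulates the Lotka-Volterra model dx/dt = 1.5x - xy, dy/dt = -3y + xy
(10 noisy replicates, sd 2), smooths the data with a periodic-kernel GP to
obtain window initial conditions, trains a second-order polynomial neural
ODE, and prints the posterior over the recovered polynomial coefficients.
Runs in a few minutes.
"""

from pinets.benchmarks import experiment_spec, generate_dataset
from pinets.pipeline import fit_ode_pipeline

ds = generate_dataset(experiment_spec("lotka_volterra", seed=1))
res = fit_ode_pipeline(ds, method="laplace", epochs=4000, seed=1,
                       smooth_on="replicate-mean")
cs = res.coeff_samples

truth = {0: {"x": 1.5, "x*y": -1.0}, 1: {"y": -3.0, "x*y": 1.0}}
for out, name in [(0, "dx/dt"), (1, "dy/dt")]:
    print(f"{name}:")
    for m, label in enumerate(cs.labels):
        col = cs.samples[:, out, m]
        t = truth[out].get(label, 0.0)
        print(f"  {label:5s} {col.mean():7.3f} +- {col.std():5.3f}   (truth {t:+.1f})")

print(f"\nNoise variance estimated at the MAP: beta^2 = {res.beta2:.2f} "
      "(the generator used sd 2, i.e. variance 4).")
print("The present terms (x and x*y in dx/dt; y and x*y in dy/dt) come out")
print("with the right signs and roughly the right magnitudes.  At this noise")
print("level a 100-point series constrains only combinations of monomials, so")
print("expect residual bias and some spurious low-order terms — equation")
print("discovery from one short noisy oscillation is genuinely hard, and the")
print("posterior should be read jointly, not term by term.")
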