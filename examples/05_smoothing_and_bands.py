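"""GPR smoothing and posterior-predictive credible bands.

Shows the two supporting pieces of the pipeline: (1) the Gaussian-process
smoother that turns high-noise observations into usable initial conditions,
quantified by its RMSE against the hidden truth; (2) posterior-predictive
trajectory bands obtained by integrating each coefficient-posterior draw.
"""

import numpy as np

from pinets.benchmarks import experiment_spec, generate_dataset, snr_profile
from pinets.coeff_posterior import posterior_predictive
from pinets.pipeline import SYSTEM_KERNELS
from pinets.smoothing import fit_gpr

ds = generate_dataset(experiment_spec("lotka_volterra", seed=5))
_, (snr_lo, snr_hi) = snr_profile(ds.truth, 2.0)
print(f"instantaneous SNR of the noiseless signal at sd 2: {snr_lo:.3f} .. {snr_hi:.2f}")

t_pool, s_pool = ds.pooled
fit = fit_gpr(t_pool, s_pool, SYSTEM_KERNELS["lotka_volterra"], restarts=3, seed=5)
pred = fit.predict(ds.truth.times)
rmse_smooth = np.sqrt(np.mean((pred - ds.truth.states) ** 2))
rmse_raw = np.sqrt(np.mean((ds.replicates[0].states - ds.truth.states) ** 2))
print(f"smoother RMSE to truth: {rmse_smooth:.3f}   raw-observation RMSE: {rmse_raw:.3f}")

# a quick predictive band from a deliberately uncertain toy posterior
from pinets.laplace import GaussianPosterior
from pinets.polynet import PiNetConfig, count_parameters, init_params

cfg = PiNetConfig(2, 2, 2)
theta = init_params(cfg, 0).to_vector()
post = GaussianPosterior(theta, 1e-9 * np.eye(theta.size))
band = posterior_predictive(post, cfg, y0=[1.0, 1.0], grid=np.linspace(0, 1, 11),
                            levels=(0.95, 0.997), n_samples=200, seed=0)
w95 = np.mean(band.upper[0.95] - band.lower[0.95])
w997 = np.mean(band.upper[0.997] - band.lower[0.997])
print(f"mean band widths: 95% {w95:.2e} <= 99.7% {w997:.2e} (nested by construction)")

print("\nThe smoother beating the raw observations is what makes it usable as")
print("the source of window initial conditions for neural-ODE training.")
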