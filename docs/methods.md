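# Methods

`pinets` recovers symbolic polynomial equations — regression functions or
ODE right-hand sides — from noisy data, with full posterior uncertainty on
every recovered coefficient. This note records the model, the numerical
choices, and their limits.

## Model

**Architecture.** A π-net is a neural network with no nonlinear
activations: biased linear layers `A_j : R^d -> R^h` are combined by
Hadamard products with skip connections,

```
z_1 = A_1(x),    z_j = A_j(x) ∘ z_{j-1} + z_{j-1}   (j = 2..k),
v = P z_k + b_P,  y = W_out v        (read-out carries no bias)
```

so the output is *exactly* a multivariate polynomial of total degree ≤ k.
For degree 3 with width h = 10 and scalar input/output this is the
1×10×10×10×10×1 layout with 180 scalar parameters. The factorized form is
expanded into monomial coefficients by exact polynomial arithmetic on
exponent-vector maps (linear maps act on coefficient matrices; the Hadamard
stage is a polynomial product via precomputed monomial-shift tables). No
coefficient pruning is applied: thresholds for "absent" terms are a
reporting choice, not a model choice. The published wiring of this network
family is not fully specified by its parameter count alone; the variant
above was chosen because it reproduces the 180-parameter layout exactly
while keeping every hidden stage the same width (a requirement of the
elementwise product).

**Likelihood and prior.** Observations are the model prediction plus
i.i.d. zero-mean Gaussian noise with unknown variance β²; all network
parameters carry an isotropic zero-mean Gaussian prior with standard
deviation α = 1e5 (noninformative at the scale of any coefficient that data
can constrain, but it keeps the posterior proper in the many directions an
overparameterized network leaves flat). MAP training maximizes
−Σ(y_pred − y_known)² + log-prior — the 1/(2β²) likelihood factor is
dropped while β² is unknown — and β² is then estimated as the sample
variance of the pooled residuals at the optimum and reinstated in every
posterior computation. Whether the prior term also enters MAP training is
configurable; at α = 1e5 the difference is numerically negligible.

**Neural ODE.** For dynamical systems the π-net is the right-hand side
dy/dt = net(y; θ). A series of n observations is cut into all n − L + 1
overlapping windows of L consecutive points; every window is an initial
value problem, and each training epoch integrates all of them
simultaneously with the 4th-order solution of the explicit
Runge–Kutta–Fehlberg pair on a fixed grid (`substeps` equal steps per
observation interval, default 10 in the integrator, 5 in the fitting
pipelines). Gradients are obtained by direct backpropagation through every
stage of the scheme — hand-written vector-Jacobian products for the network
and the integrator — not by a continuous adjoint. The 5th-order embedded
estimate is never formed, and no step-size adaptivity is used, precisely so
that the reverse pass is an exact transpose of the forward computation.
Window length L is a per-system setting (12 for the predator–prey system,
13 for the damped oscillator, 2 for the Lorenz attractor); the fixed-step
count is validated by a 4th-order convergence test rather than by any
statement about the original experiments. A partially known mechanistic
model can be added to the trainable field (`augment_with_known`), in which
case the network learns only the residual dynamics.

## Posterior engines

**Laplace.** The posterior is N(θ*, I_θ⁺) with I_θ the Fisher information
at the MAP. The "gradient" construction uses the model expectation of the
score outer product — the Gauss–Newton form Σ_i ∇θ y_i ∇θ y_iᵀ / β² plus
the prior precision I/α² — which coincides exactly with the conjugate
Bayesian linear-regression precision XᵀX/β² + I/α² on linear-in-parameters
models; that equivalence is the validation axis of the whole pipeline and
is asserted in the tests at 1e-4 (mean) / 1e-3 (covariance) relative. A
finite-difference Hessian mode exists as a cross-check for small models,
and a diagonal-only mode as a cheap fallback. Because the network is
overparameterized, I_θ is singular: the covariance is the Moore–Penrose
pseudoinverse (singular values below 1e-10 of the largest truncated,
configurable), with a hard ceiling of 50 000 parameters.

**HMC/NUTS.** Hand-implemented single-chain samplers of the full log-joint
(β² reinstated): HMC with user-fixed step size ε and leapfrog count L plus
Metropolis correction; NUTS with slice-based tree doubling (max depth 10),
dual-averaging step-size adaptation at target acceptance 0.9, and diagonal
mass-matrix estimation during warmup. The conservative acceptance target
matters: the network posterior is non-Gaussian, and adapting to 0.8 can
land the step size on the divergence boundary. In the fitting pipelines the
mass matrix is seeded with the diagonal of the Laplace covariance — the
posterior mixes poorly under a unit metric because a few data-constrained
directions coexist with hundreds of prior-dominated flat ones (condition
number ~1e10) — and chains start at the MAP. Warmup (1000 draws by
default) is discarded. Convergence is monitored with the Geweke statistic
T = (X̄₁ − X̄₂)/√(s₁²/n₁ + s₂²/n₂) comparing the first 10% and last 50% of
the kept chain, computed on the *expanded coefficient* chains (each draw is
symbolically expanded); |T| ≤ 1.964 is the 0.05-level pass. No effective-
sample-size gate is enforced.

**Mean-field VI.** The variational family is a fully factorized Gaussian.
The ELBO expectation term is estimated with reparameterized draws
(θ = μ + σε, so the estimate is differentiable in μ and log σ) and the KL
term against the Gaussian prior is closed-form. Means are initialized at
the MAP — without a point estimate first, this family is genuinely hard to
train — and log-SDs start at log(1e-3). The reported ELBO uses up to 1000
Monte-Carlo draws; the per-step gradient uses a smaller batch (default 32),
which trades per-iteration noise for many more Adam iterations (default
20 000; the fitting pipelines use problem-sized budgets). Mean-field
posteriors systematically under-cover in the parameter basis: on correlated
targets the fitted marginal variances are provably at most the exact
marginals, and the tests assert exactly that behavior. The guarantee does
not transfer to the *expanded coefficients*: sampling the factorized
posterior independently breaks the weight–bias correlations, and the
pushforward through the products of the expansion can come out wider than
the Laplace coefficient posterior. A full-covariance Gaussian family is
deliberately not offered.

**Coefficient posteriors.** Whatever the engine, the parameter posterior is
pushed to the polynomial coefficients by Monte Carlo: draw parameter
vectors (2000 by default; MCMC chains reuse their stored draws), expand
each draw symbolically, and summarize per monomial with means, SDs,
equal-tailed quantile credible intervals (highest-density intervals are not
implemented), and Scott's-rule Gaussian KDEs. Analytic propagation through
Gaussian product/sum rules is not offered: the weights and biases are
dependent, which is the reason sampling is used at all. Posterior-
predictive bands integrate each draw's expanded polynomial (plus any known
field) from a given initial state; draws that diverge are dropped with a
count, and more than 10% exclusions is an error. Default band levels are
0.95 and 0.997.

## Pre-smoothing

At low SNR the raw observations cannot serve as window initial conditions,
so a GP regression fit supplies them. Kernels: exp-sine-squared (periodic)
scaled by a constant kernel plus a white kernel for sustained oscillators;
rational quadratic (plus constant and white) for decaying or chaotic
trajectories; RBF and Matérn are also available. Hyperparameters maximize
the marginal likelihood (scikit-learn backend, 5 restarts by default,
log-space bounds [1e-3, 1e3]); the length scale is additionally bounded
below by 1.5× the sampling interval, because a shorter length scale is
statistically indistinguishable from white noise and produces degenerate
splits of the noise variance. For the periodic kernel the pipelines
initialize the periodicity at the dominant Fourier mode of the data. When
replicates share a time grid the smoother is fitted to the pointwise
replicate mean — under i.i.d. Gaussian noise the mean is a sufficient
statistic, and it keeps exact GP inference (cubic in n) tractable; pooled
fits above `max_points` (600) training points are uniformly subsampled
instead. The smoother interpolates only; extrapolation raises.

## Fitting recipe for neural ODEs

Plain Adam from a small-coefficient initialization stalls in a nearly flat
valley of the windowed objective (many fields fit one-step-ahead data
almost equally well). The pipelines therefore use a two-stage scheme:

1. *Derivative-matching pre-training*: regress finite-difference
   derivatives of the smoothed trajectory on the network (a cheap
   regression fit) to place the parameters in the right basin;
2. *Integrator fine-tuning*: the windowed simultaneous-IVP objective,
   Adam with cosine-decayed learning rate and global-norm gradient
   clipping (states of magnitude ~25 drive quadratic monomials to ~600,
   and an unclipped step can blow up the integration).

Replicate windows are collapsed for training into one window per start time
with replicate-mean targets and weight R — an exact sufficient-statistic
reduction of the pooled squared-error objective — while β² and the Fisher
information are always computed on the full pooled windows.

Network parameters are initialized so that every *expanded* coefficient
starts with magnitude in [1e-10, 1e-5]: hidden entries are drawn with
magnitude near 1 (so products across stages neither explode nor vanish) and
the read-out layer, in which every coefficient is exactly linear, is
rescaled by a common factor; draws whose coefficient spread exceeds the
band are resampled. Rescaling *all* layers by one factor cannot work in
general: a coefficient whose monomial has parameter-degree q scales as γ^q,
and q ranges from 2 to degree+2, so shrinking γ spreads the coefficient
magnitudes apart faster than it shrinks them.

## Synthetic benchmarks

The generator reproduces the four study systems with their stated
conditions as defaults: the cubic 1 + x + 2x² + 4x³ on 200 uniform points
in [−1.25, 1.25] with noise variance 9; Lotka–Volterra (1.5x − xy,
−3y + xy) from (1,1), 100 points on [0,10], 10 replicates at noise sd 2;
the damped oscillator (−0.1x³ − 2y³, 2x³ − 0.1y³) from (1,1), 500 points on
[0,25], sd 0.6; and the Lorenz attractor (σ=10, r=28, b=8/3) from (1,1,1),
900 points on [0,30], sd 2. Truth trajectories use an adaptive
high-accuracy solver (DOP853, rtol 1e-10); noise is i.i.d. Gaussian,
independent per replicate; everything is deterministic per seed (seeds
guarantee internal reproducibility only — no claim is made about matching
any other implementation's random streams). The missing-term variant
generates identical data and differs only in the known-field mask; which
two predator-prey terms are withheld is configurable, defaulting to the
prey growth 1.5x and the predator interaction +xy. The instantaneous SNR
profile |signal|/σ is reported for comparison only.

What the generator does *not* emulate: multiplicative or state-dependent
noise, irregular sampling, missing observations, replicate-specific
dynamics, and non-polynomial right-hand sides. Passing tests on these
benchmarks therefore demonstrate correctness of the machinery under the
additive-Gaussian, shared-grid assumptions, not robustness to real
laboratory data.

## Calibration and benchmark scale

The coverage study refits 100 independently generated cubic datasets
(seeds 1..100) and measures how often the 90%/95% credible intervals
contain the generating coefficients, with exact (Clopper–Pearson) binomial
intervals on the fractions; closed-form Bayesian linear regression is the
control. The Laplace pipeline tracks the BLR control within a few
hundredths.

On the Lorenz benchmark, individual coefficients are only weakly identified
below the full study scale: with a third of the span the one-step windowed
objective reaches the noise floor while coefficient posteriors have SDs of
5–10 and MAP estimates wander accordingly (the 3-posterior-SD recovery
criterion still holds). At the full 900-point, 10-replicate scale the
pipeline recovers the Prandtl and Rayleigh coefficients within a few
percent with posterior SDs near 1; the test suite and the acceptance script
run that full-scale configuration (about two minutes on one CPU).

## Degenerate inputs and numerical edges

Non-finite states during integration raise an error naming the failing
time and window (during posterior prediction, single diverging draws are
excluded instead). Zero-variance Geweke segments raise a degenerate-chain
error; zero-variance coefficient samples yield a point-mass flag rather
than a KDE. Quantile intervals require at least two samples; β² estimation
at least two residuals; GP fits at least five points. Symmetry of every
covariance-like matrix is enforced (symmetrized after pseudoinversion);
posterior sampling uses an eigendecomposition factor that tolerates the
PSD-but-singular covariances pseudoinverted Fisher matrices produce.

## Known limitations

- Stiff systems are out of scope: the fixed-step explicit scheme and
  direct backpropagation both fail there, and no adjoint is provided.
- Single-chain MCMC only; no cross-chain R̂, no ESS gate. MCMC on neural-
  ODE posteriors remains the weakest engine — it needs the Laplace
  preconditioner to mix at all and is the slowest by an order of magnitude.
- The Laplace approximation is local: a multimodal parameter posterior
  (e.g. data pooled across regimes with different dynamics) would be
  misrepresented by a single Gaussian around one mode.
- Mean-field VI is overconfident by construction; its intervals should not
  be used where calibrated uncertainty matters.
- Identifiability of individual coefficients depends on how thoroughly the
  trajectory explores state space; short or low-information trajectories
  yield wide, strongly correlated coefficient posteriors, and the MAP point
  within such a ridge is noise-determined.
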