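# Methods

## Model and energy

The generative model is a stack of Gaussian layers over an input layer:

```
p(y, x; θ) = Π_{l=0}^{L−1} N(x_l; W_l f(x_{l+1}), σ² I) · N(x_L; μ, σ² I),   x_0 = y.
```

Both inference and learning descend the energy `F = −ln p(y, x; θ)` (up to
additive constants).  Prediction errors are defined with the precision
factor inside, `ε_l = (x_l − W_l f(x_{l+1}))/σ²`, `ε_L = (x_L − μ)/σ²`, so
that the latent gradient

```
∂F/∂x_l = ε_l − f′(x_l) ⊙ (W_{l−1}ᵀ ε_{l−1})
```

is the *exact* gradient of `F` for any `σ²`; the test suite pins this to
central finite differences at 1e−5 relative error for every activation
(`linear`, `relu`, `tanh`) and both input kinds.  The derivative of `relu`
at its kink is defined as 0.  All parameters and dynamics run at double
precision: the models are small and exactness against the closed-form
oracles matters more than speed.

For binary images the input layer is Bernoulli: the `l = 0` term of `F` is
replaced by the negative Bernoulli log-likelihood of `y` given pixel means
`s(W_0 f(x_1))` (computed in the softplus form `Σ softplus(a) − yᵀa` for
numerical safety), which changes `ε_0` to `y − s(W_0 f(x_1))` and inserts
the sigmoid slope into the layer-1 gradient.  We keep the `f′(x_1)` factor
in that gradient because it is the exact derivative of the energy — common
shorthand notations drop it, which is inconsequential for the piecewise-
linear and near-linear activations typically used but would break the
finite-difference contract here.

## Inference dynamics

Sampling inference is the Euler–Maruyama discretisation of Langevin
dynamics,

```
x_l ← x_l − h ∂F/∂x_l + √(2h) n_l,    n_l ~ N(0, σ_n² I),
```

with noise drawn freshly per step, per layer, per batch element.  The chain
targets `exp(−F/σ_n²)`, so every generative layer acquires effective
variance `σ²σ_n²`; with the input clamped the latents sample the posterior,
with it free the whole network samples the joint (and `x_0` the marginal
over inputs).  MAP inference is the same descent without noise; an Adam
variant is available for the MAP phase only — adaptive preconditioning
would change the stationary distribution, so the stochastic phase always
uses plain steps (a property test enforces the `σ_n² → 0` identity between
the two steppers).

An inference run is a schedule *(warm-up K, mixing M, sampling S)*: K
noiseless warm-up steps to shorten mixing, M discarded stochastic steps,
S recorded ones.  Warm-up is optional (a CLI switch ablates it): starting
at the mode is usually but not universally helpful.  Latents initialise as
N(0, I) by default; a uniform(−10, 10) initialisation can be passed for
convergence diagnostics.  Bernoulli models keep the discrete input layer
out of the free-running dynamics; their spontaneous activity is the latent
prior, and the predicted pixel mean `s(W_0 f(x_1))` is recorded in place of
`x_0`.

## Learning

Per mini-batch: inference as above, then one optimizer step on

```
ΔW_l = (1/S) Σ_{samples} Σ_{batch} ε_l f(x_{l+1})ᵀ,   Δμ = (1/S) Σ Σ ε_L,
```

i.e. the batch is summed and the sampling phase averaged, with the learning
rate interpreted per batch.  This is Monte Carlo expectation-maximization:
with exact posterior samples the expected update equals the gradient of the
average marginal log-likelihood (verified at 10 random parameter points
against Gauss–Hermite quadrature of the closed-form marginal).  The MAP
baseline uses the same rule evaluated at the converged mode only.  The
learning optimizer is Adam by default, with plain SGD available for the
analytic consistency tests, plus optional weight decay.  Training declares
divergence (status `"diverged"`, after logging the weight growth) once any
|weight| exceeds 1e6 — for the MAP learner on over-dispersed data this is
the expected outcome, not an error.

### Default task conditions

*Gaussian task*: scalar data `y ~ N(1, 5)`, 1280 draws in 5 mini-batches of
256, linear one-latent model, `σ² = σ_n² = 1`; inference = 150 Adam warm-up
steps, 150 mixing + 1 sampling step at h = 0.02; learning = Adam, rate 0.02,
no decay, 75 epochs (375 updates).  Initial `W₀, μ ~ N(0, 1)`.

*Image task* (desk scale): 12×12 binary toy glyphs, 3 classes, 5% pixel
flips, 512 images; Bernoulli-input model with tanh latents of widths
144–32–8; inference = 30 Adam warm-up steps (rate 0.1), 50 mixing + 10
sampling steps at h = 0.03; learning = Adam at 0.01, batch 64, 25 epochs.
These sizes keep a full training run in single-digit seconds while leaving
the learned model good enough for the variability analyses; they are scaled-
down analogues of digit-image experiments, not attempts to match their
absolute metric values.

## Closed-form linear oracle

For `L = 1`, `f = id`, everything is analytic (`mcpc.linear_oracle`):
marginal `N(W₀μ, σ²σ_n²(W₀²+1))`, posterior
`N((W₀y+μ)/(W₀²+1), σ²σ_n²/(W₀²+1))`, optima
`W₀ = ±√(Σ_data/σ²σ_n² − 1)`, `μ = μ_data/W₀` (real only while
`Σ_data > σ²σ_n²`; below that the boundary solution `W₀ = 0` is returned
flagged — the model cannot represent variance below its layer floor).  The
expected-update field takes the inner posterior expectation analytically
and the outer expectation over data by Gauss–Hermite quadrature
(deterministic, so nullcline plots are bit-reproducible) or Monte Carlo.
Nullclines are defined numerically as zero contours of the field
components; no closed form is assumed.

## Synthetic stimuli

`gaussian_data` draws the scalar task data.  `toy_glyphs` draws procedural
binary templates (lines, rings, crosses on an arbitrary grid; classes are
verified at generation time to differ in ≥ 10% of pixels) and flips each
pixel i.i.d. with the stroke-noise rate, giving class-conditional
correlated pixels — the "natural stimulus" class for the cortical analyses.
`gratings` produces binarised sinusoids (threshold at the mean, uniform
phase, 16 orientations by default); `binary_noise` i.i.d. Bernoulli pixels.
Every generator is a pure function of (parameters, seed).  What these
stimuli do *not* emulate: grey levels, occlusion, scale/position jitter,
and the within-class shape variability of handwritten digits — so passing
tests demonstrate the mechanisms (posterior sampling, variance learning,
variability quenching, similarity specificity), not performance on natural
data.

## Cortical analyses

*Variability quenching*: for a batch of stimulus onsets the network runs
free, then clamped; temporal variability is the ddof-1 standard deviation
over a sliding window (cumulative-sum implementation), averaged over latent
neurons, with s.e.m. across onsets.  The noiseless baseline uses one
persistent optimizer per phase so its adaptive MAP descent actually
converges; its variability collapses to zero away from the init and onset
transients, while the sampler's drops from prior-level to posterior-level
at onset.

*Spontaneous-vs-evoked similarity*: evoked activity of a few fixed
first-layer neurons is recorded at steady state and pooled across all
stimuli of a class (the "average evoked distribution" is this mixture);
spontaneous activity of the same neurons is recorded in free running.  The
two sample sets are compared with the 1-nearest-neighbour KL estimator
(`(d/n) Σ ln(s₁/r₁) + ln(m/(n−1))`), ties broken by a 1e−12 jitter with a
fixed seed.  Degenerate (zero-variability) spontaneous sets make the
estimate diverge as the jitter shrinks — the correct verdict for the MAP
baseline, asserted as unbounded growth rather than a literal infinity.

*Decoding*: a multinomial logistic decoder maps latents to class
probabilities; coordinates are the convex combination of K unit-circle
anchors at angles `π/2 − 2πk/K` (first class on top, clockwise) — a plotting
convention only.

## Numerical choices and known limitations

- **Discretisation bias.** The unadjusted Langevin chain at step h has
  stationary variance inflated by `1/(1 − hκ/2)` on a mode of curvature κ.
  For the Gaussian task κ = (W₀²+1)/σ², so at the default h = 0.02 the
  sampled posterior is ~2% wide near the optimum of the Σ = 5 task but ~11%
  wide when the optimal weight reaches 3 (Σ/σ²σ_n² = 10).  Learning
  equilibrates where the *discrete* chain's moments balance, which sits
  slightly below the continuous-time optimum; Adam's sign-like response to
  skewed gradient noise adds a further small downward shift.  Measured
  effect: learned |W₀| ≈ 1.90 vs 2 at Σ/σ²σ_n² = 5, and ≈ 2.7 vs 3 at
  Σ/σ²σ_n² = 10 (equivalently σ_n² = 0.5 on the Σ = 5 task).  The tests
  treat the discrete fixed point — solved independently from the moment
  equations — as the quantitative oracle at high curvature, and near the
  noise ceiling (σ_n² ≥ Σ/σ²) the learned weight hovers within ~0.3 of zero
  at Adam's stochastic equilibrium rather than collapsing exactly.
- **Batch-means errors.** Moments of autocorrelated trajectories are
  reported with batch-means standard errors (20 blocks); distributional
  tests thin the chain past its autocorrelation time.
- **Marginal log-likelihood.** The Monte Carlo estimator averages
  conditional likelihoods over prior latent draws in log space
  (log-sum-exp) and includes the 1/n normalisation inside the logarithm, so
  the single-datum linear-model value matches the closed form; printed
  variants that omit the normaliser differ by `ln n` per datum.
- **Masked completion** treats missing pixels as extra latents optimised
  jointly with the network state by noiseless descent; Bernoulli pixels are
  parameterised by logits so completions stay in (0, 1).
- **Seeding.** All experiment randomness derives from one master seed via
  SHA-256-based purpose tags (`seed_split`), each child below 2³¹; batch
  elements share one generator and evolve independently.
- **Serialization.** Models, trajectories and stimulus batches are `.npz`
  containers with a JSON header; array round-trips are bit-exact.
- Not implemented: learned precision matrices, convolutional or spiking
  layers, momentum/preconditioned Langevin samplers, closed-form oracles
  for deep or nonlinear models (intractable), and image-realism metrics
  that require pretrained reference networks.
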