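# Methods

## Model

`latentspike` infers a one-dimensional latent dynamical system from
trial-structured spike trains. The latent state obeys the Langevin
equation

    dx = -D Φ'(x) dt + √(2D) dW,     x ∈ [-1, 1],

with potential Φ(x), noise magnitude D (units x²/s; the drift is scaled
by D so the equilibrium density exp(-Φ) is noise-invariant), and
absorbing boundaries at ±1: the first passage of either boundary ends the
trial and defines the reaction time. Each trial starts from
x₀ ~ p₀(x). Every neuron i fires as an inhomogeneous Poisson process
with rate λᵢ(t) = fᵢ(x(t)) through a non-negative tuning function
fᵢ(x); in population models all neurons share one x(t), and the tuning
functions jointly define the embedding geometry of the latent variable in
rate space.

Optimization runs over unconstrained auxiliaries: the force
F(x) = -Φ'(x) (one per stimulus condition), F₀ = p₀'/p₀, and
Fᵢ = fᵢ'/fᵢ with the boundary rate Cᵢ = fᵢ(-1) ≥ 0. The
reconstructions (cumulative integration plus normalization) guarantee
∫p₀ = 1, p₀ ≥ 0 and fᵢ ≥ 0 by construction. The integration constant
of Φ is fixed by ∫exp(-Φ)dx = 1; only potential differences are
meaningful.

## Likelihood

A trial is a marked point process {t₀, (t₁,i₁), …, (t_N,i_N), t_E}.
Its joint density with the first passage at t_E factorizes into the
initial density, per-ISI transition operators, spike emission factors
fᵢ(x) at spike times, and a terminal boundary-flux (absorption) factor.
The transition density during an ISI satisfies the modified
Fokker–Planck equation

    ∂p/∂t = -D ∂x(F p) + D ∂²x p - Σᵢ fᵢ(x) p ≡ -Ĥ p,

whose decay term removes trajectories inconsistent with observing no
spikes; absorbing boundary conditions remove trajectories that reach a
boundary early, and the absorption factor D|∂x p| at ±1 restricts to
trajectories that terminate on a boundary exactly at t_E. The
reaction-time-only marginal L_tE (same chain without spikes and without
the decay term) converts the joint likelihood into the spikes-only
("normalized") likelihood L/L_tE used for comparisons with PSTH
baselines; whether L_tE conditions on the reached boundary or on either
boundary is ambiguous in principle; both are available
(`te_boundary`, default "either").

### Discretization

All functions live on Legendre–Gauss–Lobatto nodes (default 256 for
standalone operators, 64 for fitting; endpoints coincide with the
absorbing boundaries). LGL quadrature is exact for polynomials up to
degree 2n-3 (∫x² is exact to machine precision), differentiation uses
the barycentric spectral matrix, and cumulative integrals (Φ, p₀, fᵢ
reconstructions) use left-to-right trapezoid accumulation on the same
nodes.

The generator is assembled in symmetrized form: with
φ = √w · exp(Φ/2) · p the drift–diffusion part becomes -PᵀWP (weak
form), a real symmetric negative-semidefinite matrix, and the spike-decay
term stays diagonal. One eigendecomposition per condition then gives the
exact action of exp(-Ĥ·Δt) for arbitrary ISIs at two matrix–vector
products per interval, with eigenvalues guaranteed ≥ 0 (densities never
grow). The chain is rescaled per ISI with the log-scale tracked
separately, so products over hundreds of spikes cannot underflow.

Numerical regime: the symmetrization multiplies by exp(±Φ/2), so the
assembled operator spans a dynamic range of roughly e^(2·range(Φ)).
Potentials with range(Φ) ≲ 12 (far beyond fitted values, which scale
like a few units) are handled accurately; transition-kernel entries below
the double-precision floor are treated as exact zeros when decoded in
density space.

### Gradients

Gradients of the data log-likelihood with respect to F per condition,
F₀, each Fᵢ, D and each Cᵢ are computed by an adjoint backward pass;
the derivative of the matrix exponential uses the Daleckii–Krein
divided-difference formula in the eigenbasis, and the chain rules through
the symmetrization transforms, the absorption vectors and the
normalized reconstructions are applied in closed form. The contract is
equality with central finite differences (verified to ≤1e-4 relative,
typically ~1e-6). A numba-compiled batch kernel implements the identical
arithmetic (cross-checked against the pure-numpy path to ~1e-14) and is
roughly 20× faster.

## Optimization

Negative log-likelihood is minimized with a function-space ADAM variant:
function-valued components are scaled by the running average of the
gradient's squared L2 norm (one scalar per function, not per node);
scalars D and Cᵢ use standard per-parameter ADAM and are rectified at
zero after each update (the likelihood additionally floors D at 1e-8
during evaluation). Defaults: α = 0.05 (0.01–0.05 for populations),
β₁ = 0.9, β₂ = 0.99, ε = 1e-8, 20 mini-batches per condition,
5000 epochs, 30 L-BFGS-B line searches over (D, {Cᵢ}) scheduled
log-spaced over epochs (analytic partial derivatives are supplied to the
line search). In shared optimization the batches of all conditions are
pooled and visited in random order; the condition force F^l is updated
only on its own condition's batches, shared components on every batch.
Initialization: all auxiliaries zero (flat potential, uniform p₀, flat
tuning), Cᵢ at the empirical mean rate, D = 0.1.

Two numerical choices matter and were made during development:

- **Gradient smoothing.** The collocation likelihood is insensitive to
  node-scale odd–even oscillations concentrated near the absorbing
  boundaries, and unconstrained ascent slowly populates that null space
  with a sawtooth artifact. Function-space gradients are therefore
  projected onto Legendre polynomials of degree ≤ grid_size/3 before
  the ADAM update (`FitConfig.grad_smooth_degree`). This is a
  regularization of the discretization, not of the physics: the retained
  subspace still resolves every structure the quadrature can represent.
- **Reflection gauge.** The model class is closed under x → -x and the
  likelihood is exactly invariant under mirroring (verified to ~1e-12),
  so the latent sign is a gauge freedom: independent fits may break it in
  opposite directions. `LatentModel.mirror()` implements the reflection;
  model selection aligns the second split's global orientation before
  comparing (per-condition disagreements, the genuine inconsistency
  signature, survive a global reflection), and
  `orient_to_choices` fixes the overall sign from behavioural labels
  after selection.

## Model selection

Feature complexity is the negative trajectory entropy relative to free
diffusion in a constant potential with uniform initial density:

    M = KL(p₀ ‖ uniform) + (D/4) ∫₀^∞ dt ∫ dx F²(x) p(x,t) ≥ 0,

where p(x,t) evolves under the plain drift–diffusion generator. The time
integral is done analytically through the resolvent
(∫₀^∞ p dt = Ĥ₀⁻¹ p₀), so the computation is a single linear solve;
the constant-potential reference has M = 0 exactly. The Monte-Carlo
path-integral estimate of the force term agrees within sampling error.

Trials are split even/odd (by index within condition) into two halves
fitted independently. Snapshots from the two traces are paired by nearest
complexity, and consistency is measured by the Jensen–Shannon divergence
between the models' time-dependent latent densities. The time measure over latent
densities is a genuinely open design choice; here the joint sub-probability
density over (x, t) induced by first-passage dynamics is normalized over
space–time (quadrature in x, trapezoid over an eigenvalue-derived
horizon) before the divergence, making D_JS symmetric and bounded by
ln 2. The selected model pair is the highest complexity with mean
D_JS ≤ 0.0015. Uncertainty bands are pointwise standard deviations over
2×10 selected models from 10 bootstrap samples (trials resampled with
replacement within two fixed non-overlapping groups, per condition).

Fit outcomes are classified as: **overfit** (tuning rates > 200 Hz
together with D ≥ 3 or D-scaled potential depth ≥ 20 — the runaway
regime where inflated noise is compensated by deep wells; typical good
fits have D ~ 0.2–0.6 and depth ~2), **underfit (no decision
signal)** (potential slope tilted to the same boundary in every
condition), **underfit (split disagreement)** (the two halves tilt to
opposite boundaries in some condition), else **good**. Barriers are
counted per condition from the two selected force functions: a sign
change counts if both splits hold one strict sign for 10 consecutive
nodes on one side of the change region and the opposite sign for 10 on
the other, at least 30 nodes from the boundaries (at 256 nodes; both
lengths scale proportionally at other grid sizes, implemented as
consensus-sign blocks so that brief flicker inside the change region does
not mask it).

## Decoding and validation

- **Viterbi.** Max-sum dynamic programming over grid values at the event
  times, with transition kernels from the same propagator as the
  likelihood, emission terms log fᵢ, and terminal boundary-flux scores,
  so every decoded path ends at ±1. Exact terminal ties resolve to the
  boundary on the side of the last interior state. Dense paths use
  kernel-bridge interpolation (argmax of forward × backward kernels).
- **Spike-time R².** R² = 1 - CV²_residual/CV²_total, with CV²_total
  from raw ISIs and CV²_residual from ISIs rescaled to operational time
  t' = ∫λ̂ dt (trapezoid) using the model-predicted single-trial rate.
  Conditions are analysed separately and averaged; conditions with fewer
  than 600 spikes are excluded. A constant prediction gives R² = 0
  identically; rescaling with the true rate of an inhomogeneous Poisson
  process gives a unit-rate Poisson process (CV² = 1).
- **ϕ estimator.** Point-process variability (CV² of ISIs in
  operational time) from spike-count means/variances at bin sizes T and
  2T via the renewal-theory quadratic
  ½(ϕ²-1) - (4E[N_T]-E[N_2T])ϕ + 4Var(N_T) - Var(N_2T) = 0.
  Exact Poisson moments give roots {1, 4μ-1}. The admissible root is the
  one in (0, 2] nearest the plug-in ISI CV² (both roots are reported);
  T defaults to 0.1 s and is configurable; a sensitivity check over T is
  recommended when spike counts per bin are low.
- **Choice prediction.** Choice = boundary reached by the decoded path
  at t_E; accuracy is balanced (mean of TPR and TNR). The supervised
  baseline is a cross-fitted logistic regression on spike counts in
  75-ms bins sliding at 10-ms steps, truncated 0.5 s after window start
  (42 bins per neuron), z-scored per condition per bin on the training
  half; conditions with fewer than 5 errors in either half are excluded
  when correctness labels exist.
- **LONO.** The held-out neuron's rate is its tuning evaluated along the
  path decoded from the other M-1 neurons (decay restricted to the
  observed subset), cubic-spline interpolated to its spike times, scored
  with the inhomogeneous-Poisson likelihood.
- **Unit selection.** (1) choice-sorted PSTH ≥ 15 Hz before the median
  RT, (2) ≥ 560 trials, (3) ROC-AUC choice selectivity of counts in the
  0.2–0.35 s window above threshold (0.6 default, 0.55 for lower-
  selectivity datasets).

## Simulators

- **Langevin–Poisson** (`simulate_trials`): Euler–Maruyama at
  dt = 5e-4 s with linear-bridge refinement of the crossing time (so
  reaction times are unbiased at the step size), spikes by thinning,
  trials over 10 s flagged as truncated and excluded. This is the
  inference model's own generative process, so recovery experiments have
  exact ground truth.
- **Ground-truth library.** `single_barrier_easy` /
  `single_barrier_hard`: four conditions (right/left × easy/hard) with a
  linear slope toward the correct boundary and a Gaussian barrier
  (σ = 0.25) guarding the incorrect one; easy conditions have the higher
  barrier and steeper slope (easy: slope 5, height 3; hard: slope 3,
  height 1.8; D = 0.3), a narrow p₀ (σ = 0.15) at the centre, and two
  shared tuning functions (an exponential ramp 4→44 Hz and a Gaussian
  bump peaking at 30 Hz at x = 0.3). These choices put reaction times
  and rates in the behavioural range (RT ~0.25–0.95 s, ~25 spikes per
  trial) with error rates of a few to ~15%.
- **Mean-field attractor** (Eqs. of the two-pool reduction with the
  printed parameters). Input noise is an Ornstein–Uhlenbeck current with
  a 2-ms correlation time (the white-noise limit is approached as the
  correlation time shrinks); the noise process driving error trials is a
  modelling choice here and its s.d. is configurable. The default s.d. 0.01 nA was
  calibrated once so reaction times (30 Hz threshold on a 200-ms moving
  average) fall in the behavioural few-hundred-ms range. Spikes are
  Poisson at the pool rates assigned to a configurable number of units
  per pool. Fixed points come from multi-start root finding with
  numerical Jacobians; the separatrix follows the reversed flow from the
  saddle's stable eigenvector.
- **Low-rank network.** Built exactly as printed: cosine/sine loadings,
  inputs bᵢ ~ U[-0.06, 0.06], readout by ridge regression (λ = 0.01) of
  the mean-field flow on K ≥ 100 uniformly sampled states. The
  projection identity z = Qᵀy is exact (J = MQᵀ), and the decision
  variable parametrizes the two choice trajectories by normalized
  cumulative arc length. Note that with the printed input spread the
  ReLU features have hinge lines passing within 0.06 of the origin, so
  the ridge fit reproduces the attractor flow only qualitatively
  (held-out residual ~40% of the mean target norm); the attractor
  structure and trajectories are preserved, but the flow field is not
  matched pointwise.

## What the synthetic data do and do not show

The Langevin–Poisson generator matches the inference model exactly, so
recovery experiments test estimation and selection, not model
misspecification. The mean-field simulator provides a mild
misspecification test (rates are not a function of a 1-D latent state
during the initial transient). None of the synthetic sources emulate
non-Poisson spiking history effects, slow nonstationarities across
trials, or spike-sorting artifacts; passing tests therefore demonstrate
correctness of the machinery and identifiability at realistic scale, not
robustness to every property of cortical data.

## Problem sizes and tolerances

The shipped tests run the recovery experiment at 4 conditions × 500
trials, 2 neurons, a 64-node fitting grid, 200 epochs, 10 batches per
condition and 8 line searches (a reduced-epoch version of the full
protocol; about four minutes on one core), with selection from 25
snapshots on a geometric epoch schedule. Monte-Carlo oracles use
2×10⁴–10⁵ paths and 3-s.e. tolerances; quadrature identities use
1e-6–1e-12 depending on the rule's exactness class. Known limitations:
potentials with total range beyond ~12 in Φ (far outside the fitted
regime) exceed the symmetrized operator's double-precision dynamic
range; `shared=False` with several conditions fits each condition
independently rather than carrying per-condition copies of shared
components inside one model object.
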