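# Methods

## The model

`ltvgrn` reconstructs a directed gene regulatory network for `n` genes from
`M` replicate expression time series of `T` samples each.  Regulation is
modelled with a *linear time-variant* (LTV) weight matrix: the total
regulatory input to gene `i` at sampling step `t` is

    Z_i(t) = sum_j W_ij(t) X_j(t),
    W_ij(t) = beta_ij + alpha_ij * sin(omega_i * t + phi_ij),

and the response one step later is the squashed input

    X_i(t+1) = sigma(Z_i(t)),   sigma(z) = 1 / (1 + e^-z).

`beta_ij` carries the constant (linear) part of the influence of gene `j`
on gene `i`; the single sinusoid term — a one-harmonic Fourier correction
with per-pair amplitude `alpha_ij` and phase `phi_ij` but a per-target
frequency `omega_i` — lets the linear-in-state form track nonlinear
regulation.  The model is a discrete-time recurrence; `t` is the integer
sampling index, not wall-clock time.  With typical fitted `|omega|` of
0.1–0.5 rad/step, the weights drift by less than a period across an
11-point series, which is the regime the correction term is meant for.

The squashing function is not uniquely pinned down by the model class
(only boundedness in (0,1) and monotonicity matter); the logistic sigmoid
is the standard choice in weight-matrix expression models and is the
default here, with a hook (`squash(z, fn=...)`) for alternatives.

A fitted model is reduced to a *static* network summary by time-averaging:
`W̄_ij = mean_t W_ij(t)` over the sampling grid.  This equals `beta` when
the amplitude is zero or the grid spans whole periods, and is well defined
on the short grids used here.  Entries with `|W̄_ij|` below a magnitude
threshold (default 0.5) are pruned; the sign of the survivors is read as
activation (+) or repression (−).

## Parameter estimation

Fitting minimises the multi-replicate mean squared *relative* error

    MSE = (1 / (M n (T-1))) * sum_{k,i,t>=1} ((X_cal - X_exp) / X_exp)^2,

where each replicate's first point anchors the recurrence and is never
scored.  By default `X_cal` is the free-running trajectory of the model
from the observed first point; a teacher-forcing (`one_step`) mode scores
each transition from the observed previous point instead.  Relative error
requires strictly positive observations, which the preprocessing
guarantees.  An absolute-error variant is available through
`FitnessConfig`.

The optimiser is self-adaptive differential evolution (jDE) in the
DE/rand/1/bin scheme.  Each of the NP=200 individuals is the flattened
parameter vector (D = 3n²+n: alpha, beta, phi row-major, then omega) plus
its own control parameters F and CR, initialised at 0.5 and 0.9.  Before
the operators run, each individual resamples F uniformly in [0.1, 1.0]
with probability τ1 = 0.1 and CR uniformly in [0, 1] with probability
τ2 = 0.1.  Mutation adds F times a random member difference to a third
member; binomial crossover with a forced index builds the trial;
out-of-bounds components are clamped to the boundary; greedy selection
keeps the trial on ties.  Default search regions: beta ∈ [-3, 3], phi and
omega ∈ [-π/2, π/2]; alpha ∈ [-10, 10] for the 5-gene benchmark and
[-5, 5] for the cAMP benchmark.  (A sign flip of alpha can be absorbed by
the phase, so a symmetric amplitude range adds no expressive power, only
search-space symmetry.)  The loop is fully vectorised over the
population — the objective is evaluated once per generation on an
(NP, D) array — and all draws come from one seeded generator in a fixed
order, so runs are bit-reproducible.

Because run-to-run variation is substantial (the objective is highly
multimodal), R independent seeded runs are combined by a Z-score
consensus: for each ordered pair, the mean and *sample* standard
deviation of `W̄_ij` over runs are formed, and the pair is retained iff
`|mean/std| >= Z_th` (default 1.0) and `|mean|` passes the magnitude
threshold.  Zero spread with a nonzero mean counts as perfectly
consistent and is retained.

## Benchmarks and the synthetic-data generators

**5-gene S-system benchmark.**  The data generator integrates the classic
five-gene power-law (S-system) network — production/degradation rate
constants 5–10, kinetic orders in {±1, 2} — with fixed-step RK4 (internal
step 1e-3).  The study design is M = 10 replicates of T = 11 uniform
samples (110 points per gene) on t ∈ [0, 0.5], each replicate starting
from an independent uniform initial state in [0.05, 1.0]^5 (the lower
limit keeps the power laws, whose exponents can be negative, away from 0).
Noisy conditions multiply every value by (1 + level·ε), ε ~ N(0,1), with
level 0.05 or 0.10, clipped to a small positive floor.  Observations are
then normalized per gene to (0, 1] against the maximum over all
replicates, with exact zeros replaced by 1e-4 — the scale the squashing
model emits and the preprocessing used for real expression tables.

**cAMP oscillator benchmark.**  The seven-ODE Laub–Loomis circuit of
spontaneous cAMP oscillations in aggregating *Dictyostelium discoideum*
(components ACA, PKA, ERK2, RegA, internal/external cAMP, CAR1; rate
constants k = 2.0, 0.9, 2.5, 1.5, 0.6, 0.8, 1.0, 1.3, 0.3, 0.8, 0.7, 4.9,
23.0, 4.5) is integrated from random positive initial states in
[0.1, 2.0]^7.  With these constants the system settles onto a stable
limit cycle of period ≈ 8 min; the design is 5 replicates of 10 uniform
samples over 9 minutes (50 points per gene, ≈1.3 periods), normalized per
gene to (0, 1].  The sampling window and initial-state range are package
choices (the design is otherwise unstated): the window covers slightly
more than one period so each replicate sees a full swing, and random
initial states place replicates at different phases/transients so the
replicates are not copies of one curve.

The gold standards are derived mechanically: for the S-system, edge j→i
iff the kinetic order `g_ij` or `h_ij` is nonzero (12 edges on 25 ordered
pairs — 7 cross-regulations plus 5 self-degradations); for the cAMP
circuit, the 17 edges (10 cross + 7 self-decay) of the stated wiring,
kept as a literal list in `netextract.py`.

What the generators deliberately do *not* emulate: measurement-platform
artifacts (probe biases, missing values), biological replicate
variability beyond initial conditions, and stochastic (molecular-noise)
dynamics.  Passing benchmarks therefore certifies the estimation
machinery on clean, model-generated dynamics, not performance on real
microarray data.

## Numerical choices

* RK4 is fixed-step with the internal step shrunk to divide each sampling
  interval evenly; divergence (non-finite or |x| > 1e6) raises with the
  failing time.  The integrator's 4th-order convergence is asserted in the
  tests.
* The sigmoid is `scipy.special.expit`; it saturates to exactly 0/1 in
  float64 beyond |z| ≈ 37, which the relative-error objective tolerates.
* jDE ties keep the trial, letting the population drift across plateaus;
  the mutation indices are drawn by vectorised rejection sampling, and
  determinism is guaranteed by a single generator with a documented draw
  order (control-parameter block, index block, crossover mask, forced
  indices).
* Experiment seeds spawn sub-seeds for dataset, noise and each run via
  `numpy.random.SeedSequence`, all reduced below 2^31.

## Reproduction scale and known limitations

The full study design is 10 independent runs of 10,000 generations per
condition.  The shipped experiments (tests and `scripts/acceptance.py`)
use 3 runs of 2000–3000 generations, which this implementation's
vectorised objective completes in a few minutes on one CPU; the
convergence curves flatten well before that point, so the reduced scale
is representative of the full one.

The central scientific limitation, measured with this package and
reproduced at full scale, is *structural non-identifiability* of the LTV
model under a plain MSE objective on these benchmarks: many dense weight
matrices fit the trajectories essentially equally well (the objective
plateaus near 1e-2 relative MSE, and per-gene decomposed refinement to
the 1e-3–1e-4 optimum still yields dense W̄ whose largest entries are not
all true edges).  Consequently the recovered per-run networks have high
sensitivity (≈0.8–0.9) but low specificity (≈0.15–0.3), and the Z-score
consensus trades sensitivity for specificity rather than improving both.
Users who need sparse networks from this model class should expect to add
an explicit sparsity penalty or prior — deliberately out of scope here,
where the plain-MSE formulation itself is the object of study.
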