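# Methods

## The onestep equilibrium model

The package models promiscuous ligand–receptor signalling in the BMP
pathway.  A type-A (type I) receptor `A_i`, a type-B (type II) receptor
`B_k` and a homodimeric ligand `L_j` associate in a single step into a
signalling trimer:

    A_i + B_k + L_j  <-->  T_ijk,     T_ijk = K_ijk · a_i · b_k · l_j

at steady state, where lower-case symbols are free concentrations and
`K_ijk` is the equilibrium constant of that complex (units:
concentration⁻²; the package works in one common arbitrary concentration
unit).  Each total is conserved, e.g. `A0_i = a_i + Σ_jk T_ijk`.  The
downstream phospho-SMAD readout is modelled as an efficiency-weighted sum

    signal = Σ_ijk eps_ijk · T_ijk ,

with one signalling efficiency `eps_ijk ≥ 0` per complex.  The weighted-sum
readout is the minimal choice that gives the model two free parameters per
complex — `(K, eps)` — i.e. 60 parameters at the full pathway scale of
3 type-A receptors × 2 type-B receptors × 5 ligands.  No fold-change
normalization is applied to the signal.

### Solver

`solve_equilibrium` iterates the fixed point

    a_i ← A0_i / (1 + Σ_jk K_ijk l_j b_k)     (cyclically for l and b),

with geometric damping (equivalent to linear damping of the log free
concentrations, so every iterate stays positive and exact zeros are
preserved).  The damping factor starts at 0.7 and halves whenever the
conservation residual stops shrinking.  Convergence is declared when the
worst relative conservation residual `|total − free − Σ complexes| /
(1 + total)` falls below `tol` (default 1e-10, budget 1e5 iterations).  If
the iteration stalls, a trust-region least-squares solve on the residuals
in log free concentration takes over; failure past both stages raises a
solver error carrying the residual.  On 1 000 random instances (K
log-uniform on [1e-4, 1e2], totals log-uniform over four decades) residuals
stay below 1e-10 and 1×1×1 solutions agree with an independent bisection
oracle to better than 1e-6 relative error.

## Synthetic studies

The observed panels this pipeline targets (hundreds of titration
experiments, each annotated with the assayed cell line's receptor totals)
are not redistributable, so `synthetic` generates panels with the same
statistical structure:

- **Conditioning variables**: per-experiment receptor totals drawn
  log-uniformly over one decade either side of 1 (at full scale, 3 + 2 = 5
  conditioning values per experiment).
- **Design variables**: a single-ligand dose titration; ligand identity and
  dose cycle deterministically through the dose grid (default 0.1, 1, 10).
- **Ground truth** `theta*` drawn from the prior, so it always lies in the
  support every downstream stage assumes.
- **Observation noise**: additive Gaussian with configurable sd (default
  0.05) on the signal scale — the simplest model consistent with an L2
  median-distance metric; the real assay's noise model is unknown.

Desk-scale defaults (1×1×1 shape, 24 experiments) let the entire pipeline
run in minutes on one CPU; the full scale (3×5×2, 940 experiments) is a
configuration choice, not a code path.  What the generator does **not**
emulate: batch effects, fold-change normalization, heteroscedastic assay
noise, and heterodimeric ligands.  Tests passing on these panels therefore
show that the inference machinery is sound under the stated noise model,
not that the biological model fits any particular real dataset.

## Surrogate likelihood

Independent experiments factorize the joint likelihood,
`p(x | θ) = Π_n p(x_n | θ, c_n)`, so one conditional density model of a
*scalar* response serves any panel size.  The surrogate is a conditional
Gaussian on an asinh-transformed response scale:

    asinh(x) | θ, c  ~  Normal( m(θ, c), s(θ, c)² )

with `m` a multilayer-perceptron regression (tanh, two hidden layers of 48,
Adam, least squares — exactly the Gaussian maximum-likelihood objective)
on `(log10 θ, c)` and, by default, a second MLP for the log standard
deviation fitted to log absolute residuals with the half-normal bias
correction `E[log|N(0,1)|] = −0.635`.  Design notes:

- **log10 θ conditioning** maps the six-decade log-uniform prior onto a
  box and linearizes the response's dependence on K.
- **asinh response scale** is linear near zero and logarithmic for large
  signals, so one network covers readouts spanning decades; densities
  reported in the original space include the change-of-variables Jacobian
  and integrate to one (checked by quadrature in the tests).
- **Extrapolation guard**: predicted sds are clipped to the largest
  training residual — an unbounded sd network otherwise "explains away"
  regions it has never seen and flattens the likelihood there.
- The held-out mean log-density of the trained surrogate is recorded next
  to that of a marginal-Gaussian null on the same pairs.

## Variational posterior

The posterior family is a logit-normal on the prior box: a full-covariance
Gaussian over a latent `z` (Cholesky-parametrized), pushed coordinate-wise
through a sigmoid onto `[log10 low, log10 high]^d`.  Every sample lies
strictly inside the prior support by construction.  Full covariance
matters here: the equilibrium constant and its efficiency are identified
only through their product below receptor saturation, and a mean-field
family collapses that ridge and becomes overconfident in every marginal.
Above 12 parameters the family falls back to diagonal (the Cholesky
parameter count grows quadratically).

Fitting maximizes a Monte-Carlo evidence lower bound evaluated on a
*fixed* set of base normal draws (192 by default, common random numbers),
which makes the objective a deterministic function of `(mu, L)`; L-BFGS-B
with numeric gradients then optimizes it, initialized by moment-matching
the best candidates of 512 prior draws.  The entropy and log-uniform prior
terms are analytic; only the expected surrogate log-likelihood is Monte
Carlo.  The ELBO trace is stored and non-decreasing up to optimizer
tolerance.  On a conjugate Gaussian toy with the exact likelihood
substituted for the surrogate, posterior mean and sd land within a
fraction of a percent of the closed form.

## Sequential rounds

Round 1 draws parameters from the prior; each round pairs every draw with
one experimental context (cycling through the panel), runs the simulator
once per draw — `sims_per_round` (default 512) is therefore a true
simulation budget — retrains the surrogate on all pairs accumulated so
far, and refits the variational posterior.  Later rounds draw parameters
from the current posterior, concentrating the simulation budget where the
posterior lives.  Each round records the median distance
`med(‖x₀ − x‖₂)` over posterior-predictive panel simulations and the
posterior-predictive coverage (percent of observed coordinates inside the
central 95% predictive interval; the interval level is configurable — the
metric's original definition fixes no convention).

## Structural affinities and spike-and-slab augmentation

A structure pipeline (structure prediction → docking → affinity
regression) reduces to one scalar, the dissociation constant Kd.
Conversions implemented:

- `Kstruct = −ln(Kd / reference)`, reference 1 M by default and
  configurable — the constant is dimensionless only relative to a standard
  concentration, and published affinity scales do not always state theirs;
- `ΔG = R·T·ln Kd` (R = 1.987e-3 kcal/(mol·K), T = 298.15 K defaults);
- detailed balance `ln K = −(N·G)` with scalar or vector stoichiometry;
- a binding-configuration multiplicity (2 ligand orientations × 2 receptor
  rotations = 4 for a symmetric homodimer on a mirrored receptor pair),
  applied multiplicatively to the affinity value by default, with the
  thermodynamic alternative (`+ ln m` on the log scale) as an option.

The structural prior on one equilibrium constant is the spike-and-slab
mixture `(1−α)·δ(K − Kstruct) + α·Normal(Kstruct, σ²)`, α = 0.1 by
default.  For importance weighting the Dirac spike is approximated by a
narrow Gaussian of width σ/100 (a true point mass has zero density at
every off-spike sample).  Posterior samples are reweighted by the mixture
density of their target coordinate and resampled with replacement —
so the output support is always a subset of the input support: the
augmentation can re-emphasize posterior mass, never create it.  By default
whole parameter rows are resampled together (sampling-importance-resampling
of the joint), which preserves the K–eps ridge correlation;
coordinate-only splicing is available (`paired=False`).

`sweep_spike_slab` grids spike locations (default 20…100, the upper half
of the prior box) against slab noise levels (default 1, 5, 10, 15, 20),
scores each cell by predictive median distance with a bootstrap Monte
Carlo error, and reports the unaugmented baseline alongside.  Degenerate
cells (all weights underflow) are marked invalid rather than aborting.
Because single-run comparisons are noise-dominated, improvement claims are
judged across ≥ 5 seeded replicates.

### When augmentation can and cannot help

Two structural facts shape what the sweep can show, and the package's
demonstration conditions respect both:

1. Resampling cannot move mass outside the posterior's own support, so a
   structural prior only matters when the posterior still carries genuine
   spread in the target coordinate.
2. A spike at the true value helps, and a distant spike hurts, only when
   the fitted posterior is *consistent* with the truth (covers it).  If
   the data-driven posterior has already missed the true coordinate, no
   reweighting can repair it — a limitation shared with the original
   resampling scheme.

The demonstration therefore checks, before sweeping, that the fitted
posterior's 10–90% interval covers the true coordinate (a premise check on
posterior consistency, not on any metric outcome), and evaluates the
informative spike at the known truth with small slab noise against a
spike displaced by three decades.

## Known limitations

- The factorized surrogate shares its mean-approximation error across all
  experiments of a panel; the joint likelihood is therefore overconfident
  in directions where that error varies smoothly with θ, and so are the
  posteriors (this is intrinsic to factorized surrogate likelihoods, not
  to this implementation).  Pointwise posterior density at θ* is
  accordingly not a reliable recovery diagnostic; predictive closeness is
  the recoverable form and is what the tests assert.
- In the saturated regime (K far above the dose scale) the response
  plateaus and K is unidentified from above; posteriors there legitimately
  spread toward the upper prior edge.
- Mean-field fallback above 12 parameters reintroduces ridge collapse at
  the full pathway scale; a structured covariance would be needed there.
- The readout map and the observation-noise model of the original assay
  are modelling choices (weighted sum, additive Gaussian); both are
  configurable but untested against real measurements.
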