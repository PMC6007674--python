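# Methods

This note defines the models implemented in `phylodyn`, the numerical
choices behind them, and the design decisions a user should know about.
Units: all times and branch lengths are in calendar time (years for
dated data); rates are per unit time; sequence evolutionary distance is
substitutions per site.

## 1. Time trees and data

A `TimeTree` is a strictly bifurcating rooted tree whose nodes carry
*heights*: time before the most recent sample, so the youngest tip has
height 0 and the root has the largest height. Newick input with branch
lengths is converted to heights; a tip-date table (or dates embedded in
labels as `name_2001.5`) anchors serially sampled tips, and the parser
rejects trees whose path lengths are inconsistent with the supplied
dates, as well as polytomies, duplicate taxa, and negative branches.

Alignments (FASTA or NEXUS) are compressed to unique site patterns with
weights. IUPAC ambiguity codes become partial-likelihood vectors
(e.g. `R` = {A, G}, `N` = all ones), so ambiguous and missing bases are
marginalized exactly rather than discarded.

## 2. Substitution models

Nucleotide evolution is a reversible CTMC with generator `Q` scaled so
that the expected substitution rate at stationarity is 1; branch
`P(t) = exp(Q·r·c·t)` then takes `t` in time units, `c` the clock rate
(subst/site/time), `r` a relative site-rate multiplier.

- **HKY**: transition/transversion ratio κ (default prior
  LogNormal(1, 1.25)), stationary frequencies π either empirical
  (default), estimated with a Dirichlet-like simplex kernel, or fixed.
  At κ = 1 and equal π it reduces to Jukes–Cantor,
  `P_ii(t) = 1/4 + 3/4·e^(−4t/3)`.
- **GTR**: six exchangeabilities with Gamma(1, 1) priors.
- **Rate heterogeneity**: discrete-gamma with k categories (default 4),
  shape α (prior Exp(2)); category rates are the means of the k
  equal-probability gamma slices and are renormalized to mean 1.

Matrix exponentials use the spectral decomposition of the symmetrized
generator when the model is reversible, with a batched einsum over all
branch lengths at once; non-diagonalizable generators fall back to
`scipy.linalg.expm` per branch. Rows are clipped to [0, 1] and
renormalized to guard against roundoff at extreme branch lengths.

## 3. Sequence likelihood

Felsenstein pruning over compressed patterns, in linear space (no
per-site log rescaling is needed at the problem sizes this package
targets; extreme-branch behavior is covered by tests that drive the
likelihood to its saturation limit `Σ_sites log π`). The implementation
enumerates nodes in postorder, computes all branch transition matrices
for a rate category in one batched call, and mixes categories with
equal weights. The result is verified against brute-force enumeration
of all internal-state assignments on small trees.

## 4. Coalescent tree priors

Intervals are extracted by sorting node heights; each sampling event
opens a (possibly zero-length) interval, and each coalescence
contributes a density factor `1/Ne(t)` in addition to the exponential
survival term `exp(−∫ C(k(t))/Ne(t) dt)` with `C(k) = k(k−1)/2`.

- **Constant**: a single `Ne > 0`, default prior `1/Ne` (improper,
  scale-invariant).
- **Skygrid**: `log Ne(t)` piecewise constant on M cells delimited by a
  fixed grid of cut points (default: equally spaced up to a cutoff near
  the starting tree's root height, last cell extending to infinity).
  The cell values γ get a first-order Gaussian-Markov random-field
  prior `p(γ | τ) ∝ τ^((M−1)/2) exp(−τ/2 Σ (γ_{i+1}−γ_i)²)` with
  precision τ ~ Gamma(0.001, 0.001). Optional covariates enter as a
  mean shift: the GMRF smooths `γ − Zβ`, with β ~ N(0, 10) on
  standardized columns. We deliberately model covariates only through
  this mean shift (not through the precision), keeping the prior
  Gaussian and the β updates simple; with M = 1 the skygrid collapses
  exactly to the constant model.

## 5. Discrete-trait diffusion and the GLM

A trait with K observed states evolves by a CTMC whose off-diagonal
rates are log-linear in P per-ordered-pair predictors:

`q_ij ∝ exp( Σ_p δ_p β_p z_{ij,p} )`, normalized to one expected
transition per unit time at the uniform distribution, and scaled by a
trait clock rate. Predictors are standardized (log-transform is the
caller's choice), and the design is *asymmetric by default*: rows are
ordered pairs (i→j distinct from j→i), because the common use case
(directional flux predictors) is asymmetric; symmetric designs are
just a special case obtained by duplicating values.

Spike-and-slab selection (BSSVS): each predictor has an inclusion
indicator `δ_p ~ Bernoulli(q)` (default q chosen so the prior expected
number of active predictors is 1) updated by bit-flip moves, and
`β_p ~ N(0, 2)`. Predictor support is reported as a Bayes factor
`BF_p = [p̂/(1−p̂)] / [q/(1−q)]` from the posterior inclusion frequency
p̂; a saturation warning is raised when p̂ is at the Monte Carlo
boundary.

**Markov jumps and rewards.** For a branch of length t with endpoint
states (a, b) the conditional expected number of labeled transitions
and the conditional expected dwell time are computed two independent
ways: (i) exact eigendecomposition integrals of
`∫ P(s) L P(t−s) ds` type, and (ii) uniformization. Posterior
accounting over a tree uses stochastic mapping: endpoint-conditioned
path sampling by uniformization bridges, with path events stored as
fractions of the branch duration. Dwell-time rewards on any partition
of states sum exactly to the branch length, and tree-wide dwell times
partition the tree length.

Missing tip states are marginalized by summing the trait likelihood
over states (log-sum-exp), not imputed.

## 6. Continuous traits

d-dimensional Brownian motion with rate matrix Σ (symmetric positive
definite, validated at construction): the displacement along a branch
of duration t is N(0, Σ·t). The likelihood integrates the root state
against N(μ0, v0·Σ) (or treats it as fixed when v0 = 0), computed by
postorder pruning with per-node mean/variance accumulation. It agrees
with the dense multivariate normal whose covariance is
`kron(C + v0·11ᵀ, Σ)`, C the matrix of shared path lengths to the
root.

## 7. MCMC

The model is a parameter graph: named parameters with bounds and
transforms, prior terms, and likelihood terms with declared parameter
dependencies so only affected terms are recomputed after a proposal.
Kernels:

- Scale (multiplier) and random-walk moves for scalars; vector walks
  for blocks (skygrid γ, GLM β); simplex moves for frequencies;
  bit-flips for indicators.
- An adaptive multivariate-normal kernel (log/logit-transformed as
  needed) that learns its covariance from the accepted history after a
  burn-in count, with Robbins–Monro scale adaptation toward 23.4%
  acceptance.
- Tree moves: node-height scaling, root-height scaling, uniform
  internal-height draws, subtree-slide, and narrow exchange, each with
  explicit Hastings corrections. Subtree-slide freezes its slide
  window before proposing and rejects root demotions that the reverse
  move could not undo; prior-only simulation of trees against direct
  coalescent simulation is part of the acceptance batteries.

Convergence diagnostics: effective sample size by Geyer's initial
monotone positive sequence; constant traces warn and report n, chains
shorter than 10 samples are rejected. Burn-in is always an explicit
argument (`burnin_fraction` or a sample count) — there is no silent
default discard anywhere in the package, so every reported summary
states its burn-in.

## 8. Marginal likelihoods

A power-posterior ladder tempers only the likelihood:
`p_β ∝ likelihood^β · prior`, with rungs at quantiles of Beta(0.3, 1)
so they crowd near the prior (β = 0), where the integrand varies
fastest.

- **Path sampling (PS)**: trapezoidal integration of E_β[log L].
- **Stepping-stone (SS)**: telescoping product of importance-sampling
  ratios between adjacent rungs (log-sum-exp stabilized); with a
  single stone it reduces exactly to prior importance sampling.
- **Generalized stepping-stone (GSS)**: a working distribution —
  independent normals on transformed scales (log for positive, logit
  for bounded parameters), moment-matched to a pilot posterior run
  with standard deviations inflated by √2 — replaces the prior as the
  reference, shortening the path. GSS runs with the tree topology and
  node heights fixed at the pilot run's last state: a tractable
  normalized reference over tree space is out of scope, and fixing the
  tree keeps the reference proper. PS/SS do not fix the tree.

All three are validated against the conjugate normal–normal closed
form `log m = C + B²/(2A) − (n/2)·log(2πσ²) − ½·log(v0·A)` with
`A = n/σ² + 1/v0`, `B = Σy/σ² + m0/v0`,
`C = −Σy²/(2σ²) − m0²/(2v0)`.

## 9. Simulators

`simulate` draws coalescent trees (constant or skygrid, contemporaneous
or serial sampling by inverse-transform of the time-rescaled
coalescent), evolves sequences site-by-site with the same CTMC code
path used for inference, realizes discrete-trait histories by Gillespie
simulation (returning both tip tables and full path realizations), and
draws Brownian tips by preorder accumulation. `simulate_all` writes a
complete small dataset (FASTA, dates, discrete traits, predictors,
continuous traits, true tree) with the seed recorded in every header;
outputs are text and deliberately small.

The simulators are realistic for the package's target regime —
tens of taxa, hundreds to thousands of sites, single-digit trait state
spaces — and intentionally simple beyond it: no recombination, no
selection, no rate autocorrelation, no sampling-through-time bias
models. Verification studies in `scripts/acceptance.py` use scaled-down
designs (e.g. 20 replicates of 20 taxa × 1000 sites for coverage; a
fixed 50-tip tree for predictor selection) chosen so the full battery
runs on one CPU core in minutes while keeping the Monte Carlo error
bars meaningful; the design constants and seed-derivation rule
(`(seed·1000003 + k) mod 2³¹`) are in that script.

## 10. Configuration and provenance

The YAML configuration groups `data`, `partitions` (each with
substitution, site-rate, and clock blocks; `links` share substitution
or clock parameters across partitions), `coalescent`, `traits_model`,
`hierarchical`, and `mcmc`. The predictor table defines the trait
state space: its rows must be the lexicographically ordered ordered
pairs of the state labels appearing in its `from`/`to` columns, and
tip states outside that space are an error. Every log file starts with
header lines recording the package version, a 12-hex-digit hash of the
canonicalized configuration, and the RNG seed, so a run is
reproducible from its own output.
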