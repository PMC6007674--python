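# phylodyn

Desk-scale Bayesian phylodynamic inference in pure Python. `phylodyn`
jointly infers time-scaled phylogenies and evolutionary parameters from
dated molecular sequence data, and layers discrete- and continuous-trait
diffusion models on top of the inferred trees. It is a compact,
well-tested statistical core for the standard Bayesian phylodynamics
workflow: substitution models, strict molecular clocks, coalescent tree
priors, trait evolution with covariate selection, MCMC, and
marginal-likelihood estimation for model comparison.

## The statistical model

Given an alignment `Y` with tip sampling dates, a discrete trait vector
`T` (for example, sampling location), and optional continuous traits
`X`, the package targets the joint posterior

```
p(tree, θ, φ | Y, T, X) ∝ p(Y | tree, θ) · p(T | tree, φ) · p(X | tree)
                          · p(tree | Ne(·)) · p(θ) p(φ) p(Ne(·))
```

with the following components, each implemented in its own module:

- **Sequence likelihood** `p(Y | tree, θ)` — Felsenstein pruning over
  compressed site patterns with HKY or GTR rate matrices, discrete-gamma
  rate heterogeneity, and a strict clock (`treelikelihood`,
  `substmodel`).
- **Coalescent tree prior** `p(tree | Ne(·))` — constant population
  size, or a skygrid: piecewise-constant `log Ne` on a time grid with a
  Gaussian-Markov random-field smoothing prior and optional
  time-varying covariates (`coalescent`).
- **Discrete-trait diffusion** `p(T | tree, φ)` — a continuous-time
  Markov chain among K states whose log rates are a linear model in
  per-pair predictors, `log q_ij = Σ_p δ_p β_p z_{ij,p}`, with
  spike-and-slab indicators `δ_p` so that predictor support is measured
  by Bayes factors; plus Markov jump counts and dwell-time rewards,
  computed either exactly (spectral integrals, uniformization) or by
  stochastic mapping (`traits`).
- **Continuous-trait diffusion** `p(X | tree)` — multivariate Brownian
  motion along the tree, evaluated by a pruning algorithm that matches
  the dense multivariate-normal likelihood (`traits`).
- **Inference** — Metropolis–Hastings with scale, random-walk, simplex,
  bit-flip, vector-walk, and adaptive multivariate-normal kernels, and
  a set of reversible tree moves on node heights and topology (`mcmc`).
- **Model comparison** — path sampling, stepping-stone sampling, and
  generalized stepping-stone with a fitted working distribution, all
  over a shared power-posterior ladder (`marginal`).
- **Simulation** — coalescent tree simulation with serially sampled
  tips, sequence evolution, discrete-trait realizations, and Brownian
  traits, used both for validation and for generating worked datasets
  (`simulate`).

## Worked example

Simulate a small dated dataset, run a joint analysis from a YAML
configuration, and summarize the chain:

```sh
phylodyn simulate --out data --seed 7 --taxa 8 --sites 200
```

`analysis.yml`:

```yaml
data:
  alignment: data/sequences.fasta
  dates: data/dates.tsv
partitions:
  - name: all
    substitution: {model: hky}
    site_rates: {categories: 4}
    clock: {rate: 0.005}
coalescent: {kind: constant}
mcmc: {chain_length: 20000, log_every: 20}
```

```sh
phylodyn run analysis.yml --seed 1
# wrote analysis.log (1000 rows)
# wrote analysis.trees (1000 trees)

phylodyn summarize analysis --burnin 0.2 --mcc-out mcc.nwk
# analysis.log: 1000 rows, 800 after burn-in
# parameter                             mean       ESS
# posterior                         -608.771       5.4
# likelihood                        -582.544      69.6
# prior                             -26.2275       4.7
# subst_all.kappa                    3.32902     482.4
# subst_all.alpha                     1.6641      56.7
# clock_all.rate                  0.00482707       5.4
# coalescent.Ne                      14.4832       7.5
# tree.root_height                   28.8583       4.9
# tree.length                        77.3293       4.4
# wrote MCC tree (1000 input trees) to mcc.nwk
```

(A 20,000-step chain is a smoke run; the low ESS values for the tree
and its hyperparameters are the expected signal to run longer.)

Marginal likelihood for the same model by stepping-stone sampling:

```sh
phylodyn mltest analysis.yml --estimator ss --rungs 8 --samples 300 --burnin 100 --seed 2
# log marginal likelihood (ss, 8 rungs): -614.9111
```

The same functionality is available as a library; see `docs/methods.md`
for the model definitions and `tests/` for focused usage examples of
every public function.

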