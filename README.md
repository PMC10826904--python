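# metanorm

Bayesian normalization of NanoString nCounter gene-expression data with
informative, meta-analytically elicited priors.

## The problem

The nCounter platform reports integer read counts per probe without
amplification and is widely used on formalin-fixed, paraffin-embedded
(FFPE) tissue, where storage degrades mRNA. Counts must therefore be
normalized for background, lane and degradation effects before analysis.
Each cartridge carries four probe classes: **positive controls** with
known spiked-in RNA amounts (128 down to 0.125 fM), **negative controls**
with no target, **housekeeping genes**, and the **regular genes** of
interest.

The normalization model is a system of random-coefficient regressions on
the log10 scale. For sample *i*:

```
Y+_ip ~ N(a_i + b_i X+_p            + d+_p, sigma_e^2)     positive probes
Y-_in ~ N(a_i + b_i c               + d-_n, sigma_n^2)     negative probes
Y*_ih ~ N(a_i + b_i (phi_i + k*_ih) + d*_h, sigma_e^2)     housekeeping
Y_ir  ~ N(a_i + b_i (phi_i + k_ir)  + d_r,  sigma_e^2)     regular genes
```

with `a_i ~ N(mu_a, sigma_a^2)`, `b_i ~ N(mu_b, sigma_b^2)`,
`k_ir ~ N(lambda_r, sigma_k^2)`, and the per-sample degradation levels
`phi_i` constrained to sum to zero. The latent `kappa` values — per
sample, per gene log10 RNA amounts before degradation — are the
normalized output. A Gibbs sampler with conjugate full conditionals
explores the posterior.

Two things make this implementation stable and fast to converge:

1. **Meta-analytic priors.** Instead of eliciting priors for the global
   intercept/slope means from the dataset being normalized (a jackknife
   on the positive probes, available here as a baseline via
   `jackknife_priors`), the defaults are informative priors from a
   multi-study hierarchical meta-analysis of positive-control
   regressions: `mu_a ~ N(2.357, 0.041)` and `mu_b ~ N(0.952, 0.003)`.
   The meta-analysis model itself (`metanorm.meta`) fits
   `Y_ijk = a_ik + b_ik X+_j + s_jk + delta_ijk` across studies *k*, with
   study-level bivariate-normal coefficient layers, inverse-Wishart
   covariance priors, and probe effects `s_jk` constrained to
   `sum_j s_jk = 0` and `sum_j s_jk X+_j = 0` for identifiability.
2. **Identifiability constraints and fixed updates.** The positive and
   negative probe deviations are restricted to their sum-to-zero
   subspaces (exact conjugate updates in an orthonormal basis of the
   constraint nullspace), and the gene means `lambda` and degradation
   levels `phi` can be updated by deterministic full-conditional means
   each sweep. Both enhancements markedly improve convergence and are
   individually switchable.

A low-memory mode (`rolling_run`) folds the kappa draws into online
mean/variance accumulators, so memory is O(1) in chain length.

## Worked example

```python
import numpy as np
from metanorm import (NormConfig, NormSimConfig, percent_change,
                      run_metanorm, simulate_ncounter)

# a 28-sample FFPE-like study: 6 positive, 8 negative, 7 housekeeping
# probes and 83 regular genes, with known ground truth
dataset, truth = simulate_ncounter(NormSimConfig(), (28, 6, 8, 7, 83), seed=7)

config = NormConfig(n_chains=2, n_draws=3000, burn_in=1000, seed=11)
store, result = run_metanorm(dataset, config)

err = result.kappa_mean[:, 7:] - truth.kappa_reg   # regular genes
print("kappa matrix shape:", result.kappa_mean.shape)
print("mean abs error vs truth: %.4f" % np.abs(err).mean())
print("mean bias: %+.4f" % err.mean())
print("count-scale change: %+.2f%%" % (100 * percent_change(err.mean())))
print("c posterior mean: %.3f (truth %.2f)" % (result.c_mean, truth.c))
```

prints

```
kappa matrix shape: (28, 90)
mean abs error vs truth: 0.0795
mean bias: -0.0135
count-scale change: -3.07%
c posterior mean: -1.475 (truth -1.50)
```

`result.kappa_mean` is the samples x (housekeeping + regular) matrix of
normalized log10 expression values; the mean absolute error of ~0.08
log10 units reflects the posterior uncertainty at this noise level, and
the mean bias is small (averaged over replicates it is within +-0.02;
see `bias_experiment`). Gelman-Rubin diagnostics for the global
parameters all round to 1.00 (`result.diagnostics.rounded()`).

The same workflow is available from the shell:

```sh
metanorm simulate --seed 7 --out-dir sim/
metanorm normalize sim/counts.csv sim/annotation.csv --out-dir norm/
metanorm diagnose norm/chain_*.csv --out-dir diag/
```

and `metanorm meta-fit <study_dir> --x-levels x.csv` runs the
meta-analysis on a directory of per-study positive-probe log-count
tables, emitting a prior-spec YAML that `normalize --priors` accepts.

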