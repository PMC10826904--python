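# Methods

## Models

### Normalization model (single study)

Counts are transformed as `Y = log10(count + 1)`. The pseudo-count keeps
the transform total (negative probes routinely read 0) and is
configurable; for counts above ~100 it changes Y by less than
`log10(1 + 1/count) < 0.005`, far below the noise scales involved.

For sample *i* the four probe classes share one linear relation between
log count and log RNA amount:

- positive probes: `Y+_ip ~ N(a_i + b_i X+_p + d+_p, sigma_e^2)` with
  `X+` the known log10 spike-in ladder (`log10(128 ... 0.125)` fM);
- negative probes: `Y-_in ~ N(a_i + b_i c + d-_n, sigma_n^2)` where the
  scalar `c` is the mean background (non-specific binding) level, and
  the negative-probe deviations get their own, larger variance;
- housekeeping and regular genes: `Y ~ N(a_i + b_i (phi_i + kappa) + d,
  sigma_e^2)` with `phi_i` the sample degradation level (sum-to-zero)
  and `kappa` the latent log10 RNA amount before degradation — the
  model's output.

Hierarchy: `a_i ~ N(mu_a, sigma_a^2)`, `b_i ~ N(mu_b, sigma_b^2)`,
`kappa_ir ~ N(lambda_r, sigma_kappa^2)`, `kappa*_ih ~ N(lambda*_h,
sigma_kappa*^2)`, probe deviations centered at zero with shared variance
`sigma_d^2` (negatives: `sigma_d-^2`). All variances carry diffuse
IG(eps, eps) priors with eps = 0.01 by default (configurable). Location
parameters without conjugate structure (`c`, `phi_i`, `lambda`) carry
"safe range" uniform priors: uniform supports wide enough to cover all
plausible values, centered at OLS-derived plug-in estimates
`X_hat = (Y - a_hat_i) / b_hat_i` with a half-width of 5 empirical SDs
(half-width multiplier configurable; explicit ranges can be supplied,
which the validation tests use).

`mu_a` and `mu_b` carry informative normal priors. The defaults,
`mu_a ~ N(2.357, 0.041)` and `mu_b ~ N(0.952, 0.003)`, are the output of
the meta-analysis below. A delete-one-sample jackknife on the
positive-probe OLS fits (`jackknife_priors`) reproduces the data-based
baseline behaviour for comparison.

### Meta-analysis model (multi-study)

Positive probes only, because there both Y and X are known:
`Y_ijk = a_ik + b_ik X+_j + s_jk + delta_ijk`. Coefficient pairs are
bivariate normal within study, `(a_ik, b_ik) ~ N((alpha_k, beta_k),
Sigma(k))`, with `Sigma(k) ~ IW_3(I_2)` (study-specific correlation is
real and changes sign between studies, so independent univariate layers
would be wrong). Study means are `alpha_k ~ N(mu_alpha, sigma_alpha^2)`,
`beta_k ~ N(mu_beta, sigma_beta^2)`; the global means carry safe-range
uniforms and the variances IG(eps, eps). Probe effects `s_jk ~ N(t_j,
tau^2)` and their means `t_j` satisfy `sum_j s_jk = 0` and
`sum_j s_jk X+_j = 0` — residual-style identifiability constraints that
stabilize the fit without artificially informative priors. Per-probe,
per-study residual variances `sigma_jk^2` absorb the remaining
heterogeneity.

The prior handed to the normalizer follows the posterior-mean rule for
mean parameters and the posterior-median rule for variance parameters:
`N(mean(mu_alpha), median(sigma_alpha^2))` and likewise for the slope.

## Samplers

Both samplers are plain Gibbs with conjugate full conditionals, a fixed
documented sweep order, and all randomness drawn from a single
`numpy.random.Generator` per chain (chains get independent
`SeedSequence` spawns of the run seed, so runs are bit-reproducible).

Sweep order, meta-analysis: coefficients -> covariances -> study means
-> global means -> variances -> probe effects. Normalization: (a_i, b_i)
jointly -> c -> kappa -> d -> (mu_a, mu_b) -> variances -> (lambda,
phi). Gibbs correctness is order-insensitive; reproducibility is why the
order is fixed.

Numerical and structural choices:

- **Constrained updates.** Vectors restricted to `{u : sum u = 0}` or
  `{u : sum u = 0, sum u x = 0}` are updated in an orthonormal basis of
  the constraint nullspace (SVD-derived). The unconstrained full
  conditional restricted to the subspace is again normal in basis
  coordinates, so these updates are exact — unlike draw-then-project,
  which distorts the stationary distribution for non-isotropic
  conditionals. The generators do use draw-then-project, where it is
  exact because the vectors being projected are isotropic Gaussians.
- **Truncated draws.** Safe-range truncation uses inverse-CDF sampling,
  falling back to scipy's tail-stable truncated-normal sampler when the
  CDF interval underflows. The constrained `t_j` and `phi` updates
  enforce their boxes by rejection inside the subspace draw (capped;
  with realistic safe ranges the cap is never reached).
- **Inverse-Wishart.** 2x2 draws use a Bartlett decomposition on the
  shared Generator (scipy's sampler is used as an independent
  cross-check in the validation tests, not in the samplers).
- **Fixed-calculation updates** (default on): `lambda_r`, `lambda*_h`
  and `phi_i` are set each sweep to their full-conditional means, with
  `phi` recentered to sum to zero. This is a mean-field-style shortcut
  that removes three blocks of random draws per sweep; a
  distribution-equivalence test (20 seeds, rank test on posterior means
  against the pure-Gibbs variant) detects no difference on a small
  instance. The pure-Gibbs variant remains available
  (`fixed_updates=False`) and is what the joint-distribution validation
  runs.
- **Initialization.** Coefficients start at per-sample OLS estimates
  plus seeded Gaussian jitter; variances at method-of-moments values;
  probe effects at projected empirical residual means. Random starts
  differ per chain through the jitter.
- **Storage.** Global scalars are always stored per draw. Kappa draws
  are stored in full by default; in low-memory mode they are folded into
  Welford mean/M2 accumulators after burn-in (identical draw sequence,
  so rolling means match full-storage means to float round-off, and the
  online variance matches the two-pass variance).
- **Degenerate inputs.** Constant-y OLS returns slope 0 with R^2
  defined as 0; genes with all-zero counts are normalized but flagged
  unreliable rather than dropped; all-constant chains report PSRF 1.0
  with a degeneracy flag.

Default chain settings: meta-analysis 4 chains x 12000 draws, burn-in
5000, thinning every other retained draw (autocorrelation is below 5% by
lag 2, which is also what `recommend_thinning` returns on these chains).
Normalization defaults to 5000 draws with burn-in 1000 — the informative
prior and the constraints make convergence fast (well under 1000
sweeps) — while the legacy data-based-prior regime of 15000 draws
remains reachable through configuration.

## Diagnostics

`gelman_rubin` implements the classic (non-rank-normalized) PSRF:
`W` the mean within-chain variance, `B/n` the variance of chain means,
`Vhat = (n-1)/n W + B/n`, `PSRF = sqrt(Vhat/W)`, with a 95% upper bound
that scales the between-chain term by an F quantile whose denominator
degrees of freedom come from a moment-matched chi-square for `W`.
Split-chain and rank-normalized variants sit behind flags. Reporting
rounds to two decimals; raw values are preserved. Autocorrelation uses
the lag-adjusted (n - lag) denominator, so an alternating sequence has
lag-1 autocorrelation exactly -1.

## Synthetic data

The generators draw directly from the two models above and return the
full latent truth, so every sampler is testable without external data.
Defaults emulate a high-quality 28-sample FFPE lung study (I=28, P=6,
N=8, H=7, R=83) with `mu_a = 2.357`, `mu_b = 0.952`, background
`c = -1.5` (so negative probes read counts in the tens), log-scale noise
SDs of 0.06-0.14, gene means `lambda` spanning 0-3 log10 units, and
degradation spread `sd(phi) = 0.1`. These are one-time choices of
realistic magnitudes for this platform; where a published dimension or
value existed it is used verbatim. Counts are emitted as
`round(10^Y - 1)` clipped at zero, so generated files are genuine
integer count tables; the quantization this adds is bounded by
`log10(1 + 1/count)`.

What the generators do **not** emulate: lane effects beyond what
`(a_i, b_i)` capture, zero inflation, probe cross-hybridization, or any
non-Gaussian noise. Passing tests therefore demonstrate correctness of
the algorithms under the model's own assumptions — parameter recovery,
calibration, constraint satisfaction, convergence — not robustness to
real-data violations of those assumptions.

## Validation strategy

- Closed-form oracles: OLS vs explicit normal equations; projection vs
  QR; jackknife variance vs delete-one refits; quantiles vs sorting;
  PSRF vs a hand evaluation of the formula.
- A linear-Gaussian oracle for the meta-analysis: with covariances,
  variances and probe effects pinned, the posterior of `(mu_alpha,
  mu_beta)` is exactly bivariate normal; a reduced Gibbs run composed
  from the sampler's own conditional updates matches it in mean and SD.
- Joint-distribution ("getting it right") tests for both samplers:
  alternating data draws and full-conditional sweeps must preserve the
  prior. Because the resulting chain is autocorrelated, agreement is
  judged by Geweke-style z-scores on the first two moments of each
  monitored marginal with IACT-inflated standard errors; an injected
  error in a single conditional moves the z-scores by an order of
  magnitude.
- Parameter recovery and coverage: 95% credible intervals for
  `mu_alpha` cover the generating value at the nominal rate over
  replicated synthetic meta-analyses.

## Known limitations

- On noiseless degenerate instances the diffuse IG(eps, eps) prior
  floors `sigma_e^2` near `eps/df`, which slowly excites the
  data-unidentified ridge between a gene's deviation `d_r` and its mean
  `lambda_r`; with realistic noise, or with eps scaled down, the effect
  is absent.
- With few genes, `phi` and `kappa` separate only through the prior, so
  per-sample degradation estimates carry posterior uncertainty of order
  `sigma_kappa / sqrt(H + R)`; gene panels of realistic size (~90)
  identify `phi` well.
- The fixed-calculation updates are a documented approximation; exact
  inference is one flag away.
- The sampling experiments here run at desk scale (thousands of draws,
  tens of samples). Defaults for production-scale chains mirror the
  documented settings but are not exercised at full length in the test
  suite.
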