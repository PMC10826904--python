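"""Meta-analysis of multi-study positive-probe data.

Each study's log10 positive-probe counts follow a per-sample linear
regression on the known log10 spike-in amounts, with study-level
bivariate-normal coefficient distributions, inverse-Wishart covariance
priors, and probe-effect residuals constrained to sum to zero (plainly
and against the design vector) for identifiability.  A Gibbs sampler
with conjugate full conditionals yields posterior draws of the global
hyperparameters mu_alpha, mu_beta, sigma_alpha^2, sigma_beta^2, which
are summarized into informative normal priors for downstream
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .constraints import constraint_basis
from .datamodel import MetaStudyCollection, PriorSpec
from .diagnostics import ChainStore

__all__ = [
    "MetaConfig",
    "QCReport",
    "fit_sample_ols",
    "qc_screen",
    "run_meta_gibbs",
    "summarize_meta_posterior",
]

GLOBAL_PARAMS = ("mu_alpha", "mu_beta", "sigma_alpha2", "sigma_beta2")


@dataclass
class MetaConfig:
    """Chain and prior settings for the meta-analysis Gibbs sampler.

    Defaults follow the production setup: four parallel chains of 12000
    draws, burn-in 5000, thinning every other retained draw, a 3-df
    inverse-Wishart with identity scale on each study covariance, and
    diffuse IG(eps, eps) priors on variance components.  Safe-range
    uniform bounds for the global means and probe-effect means are built
    from empirical estimates (half-width ``safe_range_halfwidth_sd``
    pooled SDs) unless given explicitly.
    """

    n_chains: int = 4
    n_draws: int = 12000
    burn_in: int = 5000
    thin: int = 2
    ig_epsilon: float = 0.01
    safe_range_halfwidth_sd: float = 5.0
    iw_df: float = 3.0
    iw_scale: np.ndarray = field(default_factory=lambda: np.eye(2))
    seed: int = 0
    store_all: bool = False
    jitter_sd: float = 0.05
    mu_alpha_range: tuple[float, float] | None = None
    mu_beta_range: tuple[float, float] | None = None
    t_ranges: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_draws):
            raise ValueError("burn_in must be smaller than n_draws")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.ig_epsilon <= 0:
            raise ValueError("ig_epsilon must be positive")
        self.iw_scale = np.asarray(self.iw_scale, dtype=float)


def fit_sample_ols(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Least-squares intercept, slope and R^2 of one sample's probe ladder.

    Constant ``y`` is a degenerate but legal input (flat sample): the fit
    is (mean(y), 0) with R^2 defined as 0.  Constant ``x`` leaves the
    slope unidentifiable and raises.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must be equal-length vectors of size >= 2")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("constant x: slope is unidentifiable")
    syy = np.sum((y - y.mean()) ** 2)
    if syy == 0 or np.ptp(y) == 0:
        return (float(y.mean()), 0.0, 0.0)
    b = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    a = float(y.mean() - b * x.mean())
    ss_res = float(np.sum((y - a - b * x) ** 2))
    return (a, b, 1.0 - ss_res / syy)


def _ols_all(logY: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row OLS over a study matrix: (a_hat, b_hat, r2)."""
    xc = x - x.mean()
    sxx = np.sum(xc**2)
    yc = logY - logY.mean(axis=1, keepdims=True)
    b = yc @ xc / sxx
    a = logY.mean(axis=1) - b * x.mean()
    resid = logY - a[:, None] - np.outer(b, x)
    syy = np.sum(yc**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, 1.0 - np.sum(resid**2, axis=1) / syy, 0.0)
    return a, b, r2


@dataclass
class QCReport:
    """Advisory quality screen: flags, never exclusions."""

    per_sample: pd.DataFrame   # study_id, sample_index, r2, low_r2
    per_study: pd.DataFrame    # study_id, n, frac_low_r2, corr_ab, ci_lo, ci_hi, flags

    def flagged_studies(self) -> list[str]:
        df = self.per_study
        return df.loc[df["flag_low_r2"] | df["flag_pos_corr"], "study_id"].tolist()


def qc_screen(collection: MetaStudyCollection, r2_threshold: float = 0.95,
              low_r2_frac_limit: float = 0.2) -> QCReport:
    """Screen samples (positive-probe regression R^2 below threshold) and
    studies (fraction of low-R^2 samples; strong positive intercept-slope
    correlation, judged by a Fisher-z 95% CI excluding zero)."""
    x = collection.x_levels
    sample_rows, study_rows = [], []
    for sid, logY in collection.studies:
        a, b, r2 = _ols_all(logY, x)
        low = r2 < r2_threshold
        for i in range(logY.shape[0]):
            sample_rows.append({"study_id": sid, "sample_index": i,
                                "r2": r2[i], "low_r2": bool(low[i])})
        n = logY.shape[0]
        if n >= 3 and np.std(a) > 0 and np.std(b) > 0:
            corr = float(np.corrcoef(a, b)[0, 1])
            z = np.arctanh(np.clip(corr, -1 + 1e-12, 1 - 1e-12))
            se = 1.0 / np.sqrt(n - 3)
            ci_lo, ci_hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
            undefined = False
        else:
            corr = ci_lo = ci_hi = float("nan")
            undefined = True
        study_rows.append({
            "study_id": sid, "n_samples": n,
            "frac_low_r2": float(low.mean()),
            "corr_ab": corr, "corr_ci_lo": ci_lo, "corr_ci_hi": ci_hi,
            "corr_undefined": undefined,
            "flag_low_r2": bool(low.mean() > low_r2_frac_limit),
            "flag_pos_corr": bool((not undefined) and ci_lo > 0),
        })
    return QCReport(per_sample=pd.DataFrame(sample_rows),
                    per_study=pd.DataFrame(study_rows))


# ---------------------------------------------------------------------------
# Gibbs sampler internals
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    """Inverse-CDF draw from N(mean, sd^2) truncated to [lo, hi]."""
    za, zb = (lo - mean) / sd, (hi - mean) / sd
    pa, pb = ndtr(za), ndtr(zb)
    if pb - pa < 1e-12:
        # far tail: inverse-CDF underflows, delegate to the tail-stable
        # rejection sampler
        from scipy.stats import truncnorm
        return float(mean + sd * truncnorm.rvs(za, zb, random_state=rng))
    u = rng.uniform(pa, pb)
    return mean + sd * ndtri(u)


def _inv_wishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from IW(df, scale) for a 2x2 scale via Bartlett decomposition."""
    prec_scale = np.linalg.inv(scale)
    L = np.linalg.cholesky(prec_scale)
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(rng.chisquare(df))
    A[1, 1] = np.sqrt(rng.chisquare(df - 1))
    A[1, 0] = rng.standard_normal()
    W = L @ A @ A.T @ L.T  # Wishart(df, prec_scale)
    return np.linalg.inv(W)


def _inv_gamma(rng: np.random.Generator, shape, scale):
    return np.asarray(scale) / rng.gamma(shape, 1.0, size=np.shape(scale))


@dataclass
class _MetaState:
    a: list[np.ndarray]
    b: list[np.ndarray]
    sigma_k: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    mu_alpha: float
    mu_beta: float
    sigma_alpha2: float
    sigma_beta2: float
    tau2: float
    sigma_jk2: np.ndarray
    s: np.ndarray
    t: np.ndarray


def _empirical_setup(collection: MetaStudyCollection, config: MetaConfig):
    """Safe ranges and empirical estimates used for priors and starts."""
    x = collection.x_levels
    a_hats, b_hats, resids = [], [], []
    for _, logY in collection.studies:
        a, b, _ = _ols_all(logY, x)
        a_hats.append(a)
        b_hats.append(b)
        resids.append(logY - a[:, None] - np.outer(b, x))
    a_all = np.concatenate(a_hats)
    b_all = np.concatenate(b_hats)
    hw = config.safe_range_halfwidth_sd
    if config.mu_alpha_range is not None:
        a_range = config.mu_alpha_range
    else:
        a_range = (a_all.mean() - hw * max(a_all.std(), 1e-3),
                   a_all.mean() + hw * max(a_all.std(), 1e-3))
    if config.mu_beta_range is not None:
        b_range = config.mu_beta_range
    else:
        b_range = (b_all.mean() - hw * max(b_all.std(), 1e-3),
                   b_all.mean() + hw * max(b_all.std(), 1e-3))
    if config.t_ranges is not None:
        t_ranges = np.asarray(config.t_ranges, dtype=float)
    else:
        probe_means = np.vstack([r.mean(axis=0) for r in resids])  # K x 6
        center = probe_means.mean(axis=0)
        spread = np.maximum(np.vstack(resids).std(axis=0), 1e-3)
        t_ranges = np.column_stack([center - hw * spread, center + hw * spread])
    return a_hats, b_hats, resids, a_range, b_range, t_ranges


def _init_state(collection, config, a_hats, b_hats, resids,
                a_range, b_range, rng) -> _MetaState:
    """OLS starts with seeded Gaussian jitter; variances at moments."""
    K = collection.n_studies
    x = collection.x_levels
    a = [h + rng.normal(0, config.jitter_sd, h.size) for h in a_hats]
    b = [h + rng.normal(0, config.jitter_sd, h.size) for h in b_hats]
    alpha = np.array([v.mean() for v in a])
    beta = np.array([v.mean() for v in b])
    sigma_k = np.array([
        np.cov(np.vstack([a[k], b[k]])) + 1e-4 * np.eye(2) for k in range(K)
    ])
    mu_alpha = float(np.clip(alpha.mean(), *a_range))
    mu_beta = float(np.clip(beta.mean(), *b_range))
    sigma_alpha2 = max(float(alpha.var(ddof=1)), 1e-4)
    sigma_beta2 = max(float(beta.var(ddof=1)), 1e-4)
    Q = constraint_basis(x.size, x)
    s = np.vstack([r.mean(axis=0) @ Q @ Q.T for r in resids])
    t = s.mean(axis=0)
    tau2 = max(float(np.mean((s - t) ** 2)), 1e-6)
    sigma_jk2 = np.vstack([
        np.maximum(r.var(axis=0), 1e-6) for r in resids
    ])
    return _MetaState(a=a, b=b, sigma_k=sigma_k, alpha=alpha, beta=beta,
                      mu_alpha=mu_alpha, mu_beta=mu_beta,
                      sigma_alpha2=sigma_alpha2, sigma_beta2=sigma_beta2,
                      tau2=tau2, sigma_jk2=sigma_jk2, s=s, t=t)


def update_coefficients(state: _MetaState, collection, rng) -> None:
    """(a_ik, b_ik): bivariate normal conjugate, vectorized per study."""
    x = collection.x_levels
    Z = np.column_stack([np.ones(x.size), x])
    for k, (_, logY) in enumerate(collection.studies):
        n = logY.shape[0]
        prec_prior = np.linalg.inv(state.sigma_k[k])
        D = 1.0 / state.sigma_jk2[k]
        prec = prec_prior + (Z * D[:, None]).T @ Z
        cov = np.linalg.inv(prec)
        resid = logY - state.s[k][None, :]
        rhs = (resid * D[None, :]) @ Z \
            + (prec_prior @ [state.alpha[k], state.beta[k]])[None, :]
        means = rhs @ cov.T
        L = np.linalg.cholesky(cov)
        draws = means + rng.standard_normal((n, 2)) @ L.T
        state.a[k], state.b[k] = draws[:, 0], draws[:, 1]


def update_covariances(state: _MetaState, collection, config, rng) -> None:
    """Sigma(k): inverse-Wishart conjugacy."""
    for k in range(collection.n_studies):
        W = np.column_stack([state.a[k], state.b[k]])
        dev = W - np.array([state.alpha[k], state.beta[k]])[None, :]
        scale = config.iw_scale + dev.T @ dev
        state.sigma_k[k] = _inv_wishart(rng, config.iw_df + W.shape[0], scale)


def update_study_means(state: _MetaState, collection, rng) -> None:
    """(alpha_k, beta_k): joint bivariate normal conjugate."""
    for k in range(collection.n_studies):
        n = state.a[k].size
        prec_lik = np.linalg.inv(state.sigma_k[k])
        prec = n * prec_lik + np.diag([1 / state.sigma_alpha2,
                                       1 / state.sigma_beta2])
        cov = np.linalg.inv(prec)
        rhs = prec_lik @ np.array([state.a[k].sum(), state.b[k].sum()]) \
            + np.array([state.mu_alpha / state.sigma_alpha2,
                        state.mu_beta / state.sigma_beta2])
        mean = cov @ rhs
        state.alpha[k], state.beta[k] = rng.multivariate_normal(
            mean, cov, method="cholesky")


def update_global_means(state: _MetaState, rng, a_range, b_range) -> None:
    """mu_alpha, mu_beta: truncated-normal (safe range) conjugacy."""
    K = state.alpha.size
    state.mu_alpha = _trunc_normal(rng, state.alpha.mean(),
                                   np.sqrt(state.sigma_alpha2 / K), *a_range)
    state.mu_beta = _trunc_normal(rng, state.beta.mean(),
                                  np.sqrt(state.sigma_beta2 / K), *b_range)


def update_variances(state: _MetaState, collection, config, rng,
                     Q: np.ndarray) -> None:
    """sigma_alpha^2, sigma_beta^2, tau^2, sigma_jk^2: inverse-gamma."""
    x = collection.x_levels
    K = collection.n_studies
    eps = config.ig_epsilon
    state.sigma_alpha2 = float(_inv_gamma(
        rng, eps + K / 2, eps + 0.5 * np.sum((state.alpha - state.mu_alpha) ** 2)))
    state.sigma_beta2 = float(_inv_gamma(
        rng, eps + K / 2, eps + 0.5 * np.sum((state.beta - state.mu_beta) ** 2)))
    m = Q.shape[1]
    state.tau2 = float(_inv_gamma(
        rng, eps + K * m / 2,
        eps + 0.5 * np.sum((state.s - state.t[None, :]) ** 2)))
    for k, (_, logY) in enumerate(collection.studies):
        resid = logY - state.a[k][:, None] - np.outer(state.b[k], x) \
            - state.s[k][None, :]
        state.sigma_jk2[k] = _inv_gamma(
            rng, eps + logY.shape[0] / 2, eps + 0.5 * np.sum(resid**2, axis=0))


def update_probe_effects(state: _MetaState, collection, rng, Q: np.ndarray,
                         t_ranges: np.ndarray) -> None:
    """s_jk and t: normal full conditionals restricted to the constraint
    subspace (conjugate updates in an orthonormal basis), with the safe
    range of t enforced by rejection."""
    x = collection.x_levels
    m = Q.shape[1]
    for k, (_, logY) in enumerate(collection.studies):
        n = logY.shape[0]
        e = logY - state.a[k][:, None] - np.outer(state.b[k], x)
        d_lik = n / state.sigma_jk2[k]
        P = (Q.T * d_lik[None, :]) @ Q + np.eye(m) / state.tau2
        g = e.sum(axis=0) / state.sigma_jk2[k]
        h = Q.T @ g + (Q.T @ state.t) / state.tau2
        cov = np.linalg.inv(P)
        u = rng.multivariate_normal(cov @ h, cov, method="cholesky")
        state.s[k] = Q @ u

    K = collection.n_studies
    u_bar = (state.s @ Q).mean(axis=0)
    sd = np.sqrt(state.tau2 / K)
    for _ in range(1000):
        v = u_bar + sd * rng.standard_normal(m)
        cand = Q @ v
        if np.all(cand >= t_ranges[:, 0]) and np.all(cand <= t_ranges[:, 1]):
            state.t = cand
            break
    # else: safe range too tight for the current draw; keep previous t


def meta_sweep(state: _MetaState, collection: MetaStudyCollection,
               config: MetaConfig, rng: np.random.Generator,
               Q: np.ndarray, a_range, b_range, t_ranges) -> None:
    """One full Gibbs sweep, in the fixed order: coefficients ->
    covariances -> study means -> global means -> variances -> probe
    effects.  Mutates ``state`` in place."""
    update_coefficients(state, collection, rng)
    update_covariances(state, collection, config, rng)
    update_study_means(state, collection, rng)
    update_global_means(state, rng, a_range, b_range)
    update_variances(state, collection, config, rng, Q)
    update_probe_effects(state, collection, rng, Q, t_ranges)


def run_meta_gibbs(collection: MetaStudyCollection,
                   config: MetaConfig) -> ChainStore:
    """Run the meta-analysis Gibbs sampler.

    Returns a :class:`ChainStore` holding the four global hyperparameters
    for every chain (plus study-level parameters when
    ``config.store_all``), with burn-in/thinning metadata attached.
    """
    if collection.n_studies < 2:
        raise ValueError("meta-analysis requires at least 2 studies")
    x = collection.x_levels
    Q = constraint_basis(x.size, x)
    setup = _empirical_setup(collection, config)
    a_hats, b_hats, resids, a_range, b_range, t_ranges = setup

    K = collection.n_studies
    n_draws = config.n_draws
    draws: dict[str, np.ndarray] = {
        p: np.empty((config.n_chains, n_draws)) for p in GLOBAL_PARAMS
    }
    if config.store_all:
        draws["alpha"] = np.empty((config.n_chains, n_draws, K))
        draws["beta"] = np.empty((config.n_chains, n_draws, K))
        draws["tau2"] = np.empty((config.n_chains, n_draws))
        draws["t"] = np.empty((config.n_chains, n_draws, x.size))
        draws["s_jk"] = np.empty((config.n_chains, n_draws, K, x.size))

    seed_seq = np.random.SeedSequence(config.seed)
    chain_seeds = seed_seq.spawn(config.n_chains)
    seeds_out = []
    for c, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        seeds_out.append(int(ss.generate_state(1)[0] % (2**31)))
        state = _init_state(collection, config, a_hats, b_hats, resids,
                            a_range, b_range, rng)
        if not np.isfinite([state.mu_alpha, state.mu_beta, state.tau2]).all():
            raise RuntimeError("non-finite initialization; check input log counts")
        for it in range(n_draws):
            meta_sweep(state, collection, config, rng, Q, a_range, b_range, t_ranges)
            draws["mu_alpha"][c, it] = state.mu_alpha
            draws["mu_beta"][c, it] = state.mu_beta
            draws["sigma_alpha2"][c, it] = state.sigma_alpha2
            draws["sigma_beta2"][c, it] = state.sigma_beta2
            if config.store_all:
                draws["alpha"][c, it] = state.alpha
                draws["beta"][c, it] = state.beta
                draws["tau2"][c, it] = state.tau2
                draws["t"][c, it] = state.t
                draws["s_jk"][c, it] = state.s
    return ChainStore(draws=draws, n_chains=config.n_chains, n_draws=n_draws,
                      burn_in=config.burn_in, thin=config.thin, seeds=seeds_out)


def summarize_meta_posterior(chains: ChainStore,
                             ig_epsilon: float = 0.01,
                             safe_range_halfwidth_sd: float = 5.0,
                             ) -> tuple[PriorSpec, pd.DataFrame]:
    """Summarize post-burn-in, thinned draws of the global parameters.

    The summary table reports Q1/median/Q3/mean/SD per parameter.  The
    returned :class:`PriorSpec` follows the posterior-mean rule for mean
    parameters and the posterior-median rule for variance parameters:
    mu_a ~ N(mean(mu_alpha), median(sigma_alpha^2)) and likewise for the
    slope.
    """
    rows = {}
    for p in GLOBAL_PARAMS:
        v = chains.combined(p)
        rows[p] = {
            "Q1": float(np.quantile(v, 0.25)),
            "median": float(np.quantile(v, 0.5)),
            "Q3": float(np.quantile(v, 0.75)),
            "mean": float(v.mean()),
            "SD": float(v.std(ddof=1)),
        }
    table = pd.DataFrame(rows).T[["Q1", "median", "Q3", "mean", "SD"]]
    prior = PriorSpec(
        mu_a_prior=(rows["mu_alpha"]["mean"], rows["sigma_alpha2"]["median"]),
        mu_b_prior=(rows["mu_beta"]["mean"], rows["sigma_beta2"]["median"]),
        ig_epsilon=ig_epsilon,
        safe_range_halfwidth_sd=safe_range_halfwidth_sd,
    )
    return prior, table
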