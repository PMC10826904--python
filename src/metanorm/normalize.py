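"""Gibbs-sampling normalization of a single nCounter dataset.

The model ties all four probe classes to a shared per-sample linear
relation between log10 count and log10 RNA amount:

    positive:     Y+_ip  ~ N(a_i + b_i X+_p            + d+_p, sigma_e^2)
    negative:     Y-_in  ~ N(a_i + b_i c               + d-_n, sigma_n^2)
    housekeeping: Y*_ih  ~ N(a_i + b_i (phi_i + k*_ih) + d*_h, sigma_e^2)
    regular:      Y_ir   ~ N(a_i + b_i (phi_i + k_ir)  + d_r,  sigma_e^2)

with a_i ~ N(mu_a, sigma_a^2), b_i ~ N(mu_b, sigma_b^2), latent
expression kappa ~ N(lambda, sigma_kappa^2) per gene, probe deviations
d ~ N(0, sigma_d^2) (negative probes get their own, larger variance),
and the degradation levels phi constrained to sum to zero.  The kappa
draws — per-sample, per-gene log10 RNA before degradation — are the
normalized output.

Enhancements over the plain random-coefficient sampler: informative
normal priors on (mu_a, mu_b) elicited by meta-analysis, sum-to-zero
identifiability constraints on the positive/negative probe deviations,
deterministic ("fixed-calculation") per-sweep updates of the gene means
lambda and degradation levels phi, and a low-memory rolling-average
storage mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import constraint_basis
from .datamodel import (
    META_ANALYTIC_PRIOR,
    NCounterDataset,
    PriorSpec,
    ProbeClass,
    log_transform,
)
from .diagnostics import ChainStore, GRReport, psrf_report
from .meta import _ols_all, _trunc_normal, _inv_gamma

__all__ = [
    "NormConfig",
    "NormalizedResult",
    "jackknife_priors",
    "run_metanorm",
    "rolling_run",
    "bias_experiment",
    "percent_change",
    "export_normalized",
]

SCALAR_PARAMS = ("mu_a", "mu_b", "sigma_a2", "sigma_b2", "sigma_e2", "sigma_n2",
                 "sigma_d2", "sigma_d_neg2", "sigma_kappa2", "sigma_kappa_star2",
                 "c")


@dataclass
class NormConfig:
    """Sampler settings for normalization.

    The default mode uses the meta-analytic priors with 2 chains of 5000
    draws and burn-in 1000 (the informative prior makes convergence fast);
    ``rcr_compat`` switches to the legacy regime of 15000 draws and a
    jackknife prior supplied by the caller.  ``enforce_d_constraints``
    restricts the positive/negative probe deviations to their sum-to-zero
    subspaces; ``fixed_updates`` replaces the Gibbs draws of lambda and
    phi with deterministic full-conditional means (phi recentered).
    Safe-range overrides exist for validation runs where data-derived
    ranges are inappropriate.
    """

    n_chains: int = 5
    n_draws: int = 5000
    burn_in: int = 1000
    thin: int = 1
    priors: PriorSpec = field(default_factory=lambda: META_ANALYTIC_PRIOR)
    enforce_d_constraints: bool = True
    fixed_updates: bool = True
    low_memory: bool = False
    seed: int = 0
    jitter_sd: float = 0.05
    c_range: tuple[float, float] | None = None
    phi_ranges: np.ndarray | None = None
    lambda_hk_ranges: np.ndarray | None = None
    lambda_reg_ranges: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_draws):
            raise ValueError("burn_in must be smaller than n_draws")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class NormalizedResult:
    """Posterior summaries of the normalized expression and nuisance
    parameters, with convergence diagnostics."""

    sample_ids: list[str]
    gene_ids: list[str]               # housekeeping then regular
    kappa_mean: np.ndarray            # I x (H+R)
    kappa_sd: np.ndarray              # I x (H+R)
    phi_mean: np.ndarray
    a_mean: np.ndarray
    b_mean: np.ndarray
    c_mean: float
    d_summary: pd.DataFrame
    variance_summary: pd.DataFrame
    diagnostics: GRReport
    unreliable_genes: list[str] = field(default_factory=list)

    def kappa_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.kappa_mean, index=self.sample_ids,
                            columns=self.gene_ids)


def jackknife_priors(dataset: NCounterDataset) -> PriorSpec:
    """Delete-one-sample jackknife priors for (mu_a, mu_b).

    Per-sample OLS on the positive probes gives (a_hat_i, b_hat_i); the
    prior mean is the grand mean and the prior variance is the jackknife
    variance of the mean, (n-1)/n * sum((theta_(i) - theta_bar)^2) over
    leave-one-out means.  This is the data-based baseline that the
    meta-analytic priors replace.
    """
    I = dataset.counts.shape[0]
    if I < 3:
        raise ValueError("jackknife priors need at least 3 samples")
    y = log_transform(dataset)[:, dataset.class_slice(ProbeClass.POSITIVE)]
    a_hat, b_hat, _ = _ols_all(y, dataset.positive_levels_log10)
    spec = {}
    for name, est in (("a", a_hat), ("b", b_hat)):
        total = est.sum()
        loo = (total - est) / (I - 1)          # leave-one-out means
        var = (I - 1) / I * np.sum((loo - loo.mean()) ** 2)
        spec[name] = (float(est.mean()), max(float(var), 1e-8))
    return PriorSpec(mu_a_prior=spec["a"], mu_b_prior=spec["b"])


def percent_change(bias: float) -> float:
    """Percent change on the count scale implied by a mean log10 bias:
    10**bias - 1, as a fraction (multiply by 100 for percent)."""
    return 10.0 ** bias - 1.0


# ---------------------------------------------------------------------------
# sampler state
# ---------------------------------------------------------------------------

@dataclass
class _NormState:
    a: np.ndarray
    b: np.ndarray
    c: float
    phi: np.ndarray
    kappa_h: np.ndarray
    kappa_r: np.ndarray
    lam_h: np.ndarray
    lam_r: np.ndarray
    d_pos: np.ndarray
    d_neg: np.ndarray
    d_hk: np.ndarray
    d_reg: np.ndarray
    mu_a: float
    mu_b: float
    sigma_a2: float
    sigma_b2: float
    sigma_e2: float
    sigma_n2: float
    sigma_d2: float
    sigma_d_neg2: float
    sigma_kappa2: float
    sigma_kappa_star2: float


class _NormModel:
    """Precomputed data views and safe ranges for one dataset."""

    def __init__(self, dataset: NCounterDataset, config: NormConfig):
        I, P, N, H, R = dataset.dims
        if H == 0 and R == 0:
            raise ValueError("nothing to normalize: dataset has no "
                             "housekeeping or regular genes")
        self.dims = (I, P, N, H, R)
        Y = log_transform(dataset)
        self.Yp = Y[:, dataset.class_slice(ProbeClass.POSITIVE)]
        self.Yn = Y[:, dataset.class_slice(ProbeClass.NEGATIVE)]
        self.Yh = Y[:, dataset.class_slice(ProbeClass.HOUSEKEEPING)]
        self.Yr = Y[:, dataset.class_slice(ProbeClass.REGULAR)]
        self.x = dataset.positive_levels_log10
        self.Q_pos = constraint_basis(P, self.x)
        self.Q_neg = constraint_basis(N) if N > 1 else None
        self.Q_phi = constraint_basis(I)
        self._derive_ranges(config)
        self.a_hat, self.b_hat, _ = _ols_all(self.Yp, self.x)

    def _derive_ranges(self, config: NormConfig) -> None:
        """Safe-range uniforms centered at OLS-derived plug-in estimates
        with a halfwidth of `safe_range_halfwidth_sd` empirical SDs."""
        I, P, N, H, R = self.dims
        hw = config.priors.safe_range_halfwidth_sd
        a_hat, b_hat, _ = _ols_all(self.Yp, self.x)
        b_safe = np.where(np.abs(b_hat) > 1e-6, b_hat, 1.0)
        if config.c_range is not None:
            self.c_range = config.c_range
        elif N > 0:
            c_hat = (self.Yn - a_hat[:, None]) / b_safe[:, None]
            sd = max(c_hat.std(), 0.05)
            self.c_range = (c_hat.mean() - hw * sd, c_hat.mean() + hw * sd)
        else:
            self.c_range = (-6.0, 2.0)
        # plug-in latent RNA estimates for housekeeping/regular genes
        Xh = (self.Yh - a_hat[:, None]) / b_safe[:, None] if H else np.zeros((I, 0))
        Xr = (self.Yr - a_hat[:, None]) / b_safe[:, None] if R else np.zeros((I, 0))
        X_all = np.hstack([Xh, Xr])
        pooled_sd = max(X_all.std(), 0.05) if X_all.size else 0.5
        if config.phi_ranges is not None:
            self.phi_ranges = np.asarray(config.phi_ranges, dtype=float)
        else:
            phi_hat = X_all.mean(axis=1) - X_all.mean() if X_all.size else np.zeros(I)
            self.phi_ranges = np.column_stack(
                [phi_hat - hw * pooled_sd, phi_hat + hw * pooled_sd])
        if config.lambda_hk_ranges is not None:
            self.lam_h_ranges = np.asarray(config.lambda_hk_ranges, dtype=float)
        else:
            ctr = Xh.mean(axis=0) if H else np.zeros(0)
            self.lam_h_ranges = np.column_stack(
                [ctr - hw * pooled_sd, ctr + hw * pooled_sd])
        if config.lambda_reg_ranges is not None:
            self.lam_r_ranges = np.asarray(config.lambda_reg_ranges, dtype=float)
        else:
            ctr = Xr.mean(axis=0) if R else np.zeros(0)
            self.lam_r_ranges = np.column_stack(
                [ctr - hw * pooled_sd, ctr + hw * pooled_sd])
        self.Xh_hat, self.Xr_hat = Xh, Xr


def _init_norm_state(model: _NormModel, config: NormConfig,
                     rng: np.random.Generator) -> _NormState:
    I, P, N, H, R = model.dims
    a = model.a_hat + rng.normal(0, config.jitter_sd, I)
    b = model.b_hat + rng.normal(0, config.jitter_sd, I)
    c = float(np.clip(np.mean(model.c_range), *model.c_range))
    phi = model.phi_ranges.mean(axis=1) if I else np.zeros(I)
    phi = phi - phi.mean()
    lam_h = model.lam_h_ranges.mean(axis=1)
    lam_r = model.lam_r_ranges.mean(axis=1)
    kappa_h = model.Xh_hat - phi[:, None] if H else np.zeros((I, 0))
    kappa_r = model.Xr_hat - phi[:, None] if R else np.zeros((I, 0))
    resid_p = model.Yp - model.a_hat[:, None] - np.outer(model.b_hat, model.x)
    s_e2 = max(float(resid_p.var()), 1e-5)
    mu_a0, _ = config.priors.mu_a_prior
    mu_b0, _ = config.priors.mu_b_prior
    return _NormState(
        a=a, b=b, c=c, phi=phi, kappa_h=kappa_h, kappa_r=kappa_r,
        lam_h=lam_h.copy(), lam_r=lam_r.copy(),
        d_pos=np.zeros(P), d_neg=np.zeros(N), d_hk=np.zeros(H), d_reg=np.zeros(R),
        mu_a=float(mu_a0), mu_b=float(mu_b0),
        sigma_a2=max(float(model.a_hat.var()), 1e-4),
        sigma_b2=max(float(model.b_hat.var()), 1e-4),
        sigma_e2=s_e2, sigma_n2=max(2 * s_e2, 1e-4),
        sigma_d2=max(s_e2 / 2, 1e-5), sigma_d_neg2=max(s_e2, 1e-5),
        sigma_kappa2=0.05, sigma_kappa_star2=0.02,
    )


def _draw_bivariate(rng, means, covs_flat):
    """Vectorized draws from N(means_i, Cov_i) for 2-vectors.

    ``covs_flat`` = (c11, c12, c22) arrays; Cholesky done elementwise.
    """
    c11, c12, c22 = covs_flat
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(np.maximum(c22 - l21**2, 1e-300))
    z = rng.standard_normal((means.shape[0], 2))
    out = np.empty_like(means)
    out[:, 0] = means[:, 0] + l11 * z[:, 0]
    out[:, 1] = means[:, 1] + l21 * z[:, 0] + l22 * z[:, 1]
    return out


def norm_sweep(state: _NormState, model: _NormModel, config: NormConfig,
               rng: np.random.Generator) -> None:
    """One Gibbs sweep in the fixed order: (a_i, b_i) -> c -> kappa -> d
    -> (mu_a, mu_b) -> variances -> (lambda, phi).  Mutates ``state``."""
    I, P, N, H, R = model.dims
    x = model.x
    eps = config.priors.ig_epsilon
    we = 1.0 / state.sigma_e2
    wn = 1.0 / state.sigma_n2

    # ---- (a_i, b_i): bivariate normal conjugate, vectorized over samples
    Xh = state.phi[:, None] + state.kappa_h if H else np.zeros((I, 0))
    Xr = state.phi[:, None] + state.kappa_r if R else np.zeros((I, 0))
    # weighted design sums per sample over all probe classes
    s0 = we * (P + H + R) + wn * N
    s1 = we * (x.sum() + Xh.sum(axis=1) + Xr.sum(axis=1)) + wn * N * state.c
    s2 = we * ((x**2).sum() + (Xh**2).sum(axis=1) + (Xr**2).sum(axis=1)) \
        + wn * N * state.c**2
    yp = model.Yp - state.d_pos[None, :]
    yn = model.Yn - state.d_neg[None, :] if N else np.zeros((I, 0))
    yh = model.Yh - state.d_hk[None, :] if H else np.zeros((I, 0))
    yr = model.Yr - state.d_reg[None, :] if R else np.zeros((I, 0))
    r0 = we * (yp.sum(axis=1) + yh.sum(axis=1) + yr.sum(axis=1)) + wn * yn.sum(axis=1)
    r1 = we * (yp @ x + (yh * Xh).sum(axis=1) + (yr * Xr).sum(axis=1)) \
        + wn * state.c * yn.sum(axis=1)
    p11 = s0 + 1.0 / state.sigma_a2
    p12 = s1
    p22 = s2 + 1.0 / state.sigma_b2
    det = p11 * p22 - p12**2
    c11, c12, c22 = p22 / det, -p12 / det, p11 / det
    m0 = r0 + state.mu_a / state.sigma_a2
    m1 = r1 + state.mu_b / state.sigma_b2
    means = np.column_stack([c11 * m0 + c12 * m1, c12 * m0 + c22 * m1])
    draws = _draw_bivariate(rng, means, (c11, c12, c22))
    state.a, state.b = draws[:, 0], draws[:, 1]

    # ---- c: negative-probe background level, safe-range truncated normal
    if N > 0:
        prec = wn * N * np.sum(state.b**2)
        num = wn * np.sum(state.b[:, None] * (model.Yn - state.a[:, None]
                                              - state.d_neg[None, :]))
        state.c = _trunc_normal(rng, num / prec, np.sqrt(1.0 / prec),
                                *model.c_range)

    # ---- kappa: latent expression, normal conjugate (vectorized I x gene)
    b2we = state.b[:, None] ** 2 * we
    if H:
        prec = b2we + 1.0 / state.sigma_kappa_star2
        resid = model.Yh - state.a[:, None] - state.d_hk[None, :] \
            - state.b[:, None] * state.phi[:, None]
        mean = (state.b[:, None] * we * resid
                + state.lam_h[None, :] / state.sigma_kappa_star2) / prec
        state.kappa_h = mean + rng.standard_normal((I, H)) / np.sqrt(prec)
    if R:
        prec = b2we + 1.0 / state.sigma_kappa2
        resid = model.Yr - state.a[:, None] - state.d_reg[None, :] \
            - state.b[:, None] * state.phi[:, None]
        mean = (state.b[:, None] * we * resid
                + state.lam_r[None, :] / state.sigma_kappa2) / prec
        state.kappa_r = mean + rng.standard_normal((I, R)) / np.sqrt(prec)

    # ---- probe deviations d
    q_pos = I * we + 1.0 / state.sigma_d2
    g = we * (model.Yp - state.a[:, None] - np.outer(state.b, x)).sum(axis=0)
    if config.enforce_d_constraints:
        Qp = model.Q_pos
        mu_u = Qp.T @ (g / q_pos)
        u = mu_u + rng.standard_normal(Qp.shape[1]) / np.sqrt(q_pos)
        state.d_pos = Qp @ u
    else:
        state.d_pos = g / q_pos + rng.standard_normal(P) / np.sqrt(q_pos)
    if N:
        q_neg = I * wn + 1.0 / state.sigma_d_neg2
        g = wn * (model.Yn - state.a[:, None]
                  - state.b[:, None] * state.c).sum(axis=0)
        if config.enforce_d_constraints and model.Q_neg is not None:
            Qn = model.Q_neg
            mu_u = Qn.T @ (g / q_neg)
            u = mu_u + rng.standard_normal(Qn.shape[1]) / np.sqrt(q_neg)
            state.d_neg = Qn @ u
        else:
            state.d_neg = g / q_neg + rng.standard_normal(N) / np.sqrt(q_neg)
    q_d = I * we + 1.0 / state.sigma_d2
    if H:
        g = we * (model.Yh - state.a[:, None]
                  - state.b[:, None] * Xh_cur(state)).sum(axis=0)
        state.d_hk = g / q_d + rng.standard_normal(H) / np.sqrt(q_d)
    if R:
        g = we * (model.Yr - state.a[:, None]
                  - state.b[:, None] * Xr_cur(state)).sum(axis=0)
        state.d_reg = g / q_d + rng.standard_normal(R) / np.sqrt(q_d)

    # ---- global means: normal conjugacy with the informative priors
    m0a, v0a = config.priors.mu_a_prior
    m0b, v0b = config.priors.mu_b_prior
    prec = 1.0 / v0a + I / state.sigma_a2
    mean = (m0a / v0a + state.a.sum() / state.sigma_a2) / prec
    state.mu_a = mean + rng.standard_normal() / np.sqrt(prec)
    prec = 1.0 / v0b + I / state.sigma_b2
    mean = (m0b / v0b + state.b.sum() / state.sigma_b2) / prec
    state.mu_b = mean + rng.standard_normal() / np.sqrt(prec)

    # ---- variances: inverse-gamma conjugacy
    state.sigma_a2 = float(_inv_gamma(
        rng, eps + I / 2, eps + 0.5 * np.sum((state.a - state.mu_a) ** 2)))
    state.sigma_b2 = float(_inv_gamma(
        rng, eps + I / 2, eps + 0.5 * np.sum((state.b - state.mu_b) ** 2)))
    ssr = np.sum((model.Yp - state.a[:, None] - np.outer(state.b, x)
                  - state.d_pos[None, :]) ** 2)
    if H:
        ssr += np.sum((model.Yh - state.a[:, None]
                       - state.b[:, None] * Xh_cur(state)
                       - state.d_hk[None, :]) ** 2)
    if R:
        ssr += np.sum((model.Yr - state.a[:, None]
                       - state.b[:, None] * Xr_cur(state)
                       - state.d_reg[None, :]) ** 2)
    state.sigma_e2 = float(_inv_gamma(rng, eps + I * (P + H + R) / 2,
                                      eps + 0.5 * ssr))
    if N:
        ssn = np.sum((model.Yn - state.a[:, None] - state.b[:, None] * state.c
                      - state.d_neg[None, :]) ** 2)
        state.sigma_n2 = float(_inv_gamma(rng, eps + I * N / 2, eps + 0.5 * ssn))
    # constrained d vectors carry fewer free dimensions
    df_pos = (P - 2) if config.enforce_d_constraints else P
    ssd = np.sum(state.d_pos**2) + np.sum(state.d_hk**2) + np.sum(state.d_reg**2)
    state.sigma_d2 = float(_inv_gamma(rng, eps + (df_pos + H + R) / 2,
                                      eps + 0.5 * ssd))
    if N:
        df_neg = (N - 1) if (config.enforce_d_constraints and N > 1) else N
        state.sigma_d_neg2 = float(_inv_gamma(
            rng, eps + df_neg / 2, eps + 0.5 * np.sum(state.d_neg**2)))
    if R:
        state.sigma_kappa2 = float(_inv_gamma(
            rng, eps + I * R / 2,
            eps + 0.5 * np.sum((state.kappa_r - state.lam_r[None, :]) ** 2)))
    if H:
        state.sigma_kappa_star2 = float(_inv_gamma(
            rng, eps + I * H / 2,
            eps + 0.5 * np.sum((state.kappa_h - state.lam_h[None, :]) ** 2)))

    # ---- lambda and phi: fixed-calculation or Gibbs updates
    if config.fixed_updates:
        if H:
            state.lam_h = np.clip(state.kappa_h.mean(axis=0),
                                  model.lam_h_ranges[:, 0], model.lam_h_ranges[:, 1])
        if R:
            state.lam_r = np.clip(state.kappa_r.mean(axis=0),
                                  model.lam_r_ranges[:, 0], model.lam_r_ranges[:, 1])
        phi = _phi_mean(state, model, we)
        state.phi = phi - phi.mean()
    else:
        if H:
            sd = np.sqrt(state.sigma_kappa_star2 / I)
            km = state.kappa_h.mean(axis=0)
            state.lam_h = np.array([
                _trunc_normal(rng, km[h], sd, *model.lam_h_ranges[h])
                for h in range(H)])
        if R:
            sd = np.sqrt(state.sigma_kappa2 / I)
            km = state.kappa_r.mean(axis=0)
            state.lam_r = np.array([
                _trunc_normal(rng, km[r], sd, *model.lam_r_ranges[r])
                for r in range(R)])
        _phi_gibbs(state, model, rng, we)


def Xh_cur(state: _NormState) -> np.ndarray:
    return state.phi[:, None] + state.kappa_h


def Xr_cur(state: _NormState) -> np.ndarray:
    return state.phi[:, None] + state.kappa_r


def _phi_parts(state: _NormState, model: _NormModel, we: float):
    """Per-sample precision and score of the degradation levels."""
    I, P, N, H, R = model.dims
    prec = state.b**2 * (H + R) * we
    g = np.zeros(I)
    if H:
        g += we * state.b * (model.Yh - state.a[:, None] - state.d_hk[None, :]
                             - state.b[:, None] * state.kappa_h).sum(axis=1)
    if R:
        g += we * state.b * (model.Yr - state.a[:, None] - state.d_reg[None, :]
                             - state.b[:, None] * state.kappa_r).sum(axis=1)
    return prec, g


def _phi_mean(state: _NormState, model: _NormModel, we: float) -> np.ndarray:
    prec, g = _phi_parts(state, model, we)
    return np.where(prec > 0, g / np.maximum(prec, 1e-300), 0.0)


def _phi_gibbs(state: _NormState, model: _NormModel,
               rng: np.random.Generator, we: float) -> None:
    """Joint constrained update of phi in the sum-to-zero basis, with
    safe-range box truncation handled by rejection."""
    prec, g = _phi_parts(state, model, we)
    Qf = model.Q_phi
    P_u = (Qf.T * prec[None, :]) @ Qf
    cov = np.linalg.inv(P_u)
    mean = cov @ (Qf.T @ g)
    L = np.linalg.cholesky(cov)
    lo, hi = model.phi_ranges[:, 0], model.phi_ranges[:, 1]
    for _ in range(1000):
        u = mean + L @ rng.standard_normal(mean.size)
        cand = Qf @ u
        if np.all(cand >= lo) and np.all(cand <= hi):
            state.phi = cand
            return
    # ranges numerically too tight for the current conditional; keep phi


# ---------------------------------------------------------------------------
# main loops
# ---------------------------------------------------------------------------

def _run(dataset: NCounterDataset, config: NormConfig
         ) -> tuple[ChainStore, NormalizedResult]:
    model = _NormModel(dataset, config)
    I, P, N, H, R = model.dims
    C, T = config.n_chains, config.n_draws
    n_mon = min(I, 3)

    draws: dict[str, np.ndarray] = {p: np.empty((C, T)) for p in SCALAR_PARAMS}
    for j in range(n_mon):
        draws[f"a_{j + 1}"] = np.empty((C, T))
        draws[f"b_{j + 1}"] = np.empty((C, T))
    draws["phi"] = np.empty((C, T, I))
    draws["d_pos"] = np.empty((C, T, P))
    draws["d_neg"] = np.empty((C, T, N))
    draws["lambda_hk"] = np.empty((C, T, H))
    draws["lambda_reg"] = np.empty((C, T, R))
    if not config.low_memory:
        draws["kappa_hk"] = np.empty((C, T, I, H))
        draws["kappa_reg"] = np.empty((C, T, I, R))

    # Welford accumulators for kappa (always maintained; they are the
    # entire kappa record in low-memory mode)
    k_mean = np.zeros((I, H + R))
    k_m2 = np.zeros((I, H + R))
    k_n = 0
    acc_mean = {"a": np.zeros(I), "b": np.zeros(I)}
    acc_n = 0

    seed_seq = np.random.SeedSequence(config.seed)
    seeds_out = []
    for c_idx, ss in enumerate(seed_seq.spawn(C)):
        rng = np.random.default_rng(ss)
        seeds_out.append(int(ss.generate_state(1)[0] % (2**31)))
        state = _init_norm_state(model, config, rng)
        for it in range(T):
            norm_sweep(state, model, config, rng)
            if not np.isfinite(state.mu_a) or not np.isfinite(state.sigma_e2):
                raise RuntimeError(
                    f"chain {c_idx} diverged (non-finite draw) at sweep {it}")
            for p in SCALAR_PARAMS:
                draws[p][c_idx, it] = getattr(state, p)
            for j in range(n_mon):
                draws[f"a_{j + 1}"][c_idx, it] = state.a[j]
                draws[f"b_{j + 1}"][c_idx, it] = state.b[j]
            draws["phi"][c_idx, it] = state.phi
            draws["d_pos"][c_idx, it] = state.d_pos
            draws["d_neg"][c_idx, it] = state.d_neg
            draws["lambda_hk"][c_idx, it] = state.lam_h
            draws["lambda_reg"][c_idx, it] = state.lam_r
            if not config.low_memory:
                draws["kappa_hk"][c_idx, it] = state.kappa_h
                draws["kappa_reg"][c_idx, it] = state.kappa_r
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                k_n += 1
                kap = np.hstack([state.kappa_h, state.kappa_r])
                delta = kap - k_mean
                k_mean += delta / k_n
                k_m2 += delta * (kap - k_mean)
                acc_n += 1
                acc_mean["a"] += (state.a - acc_mean["a"]) / acc_n
                acc_mean["b"] += (state.b - acc_mean["b"]) / acc_n

    store = ChainStore(draws=draws, n_chains=C, n_draws=T,
                       burn_in=config.burn_in, thin=config.thin,
                       seeds=seeds_out)
    if config.low_memory:
        store.rolling["kappa"] = (k_mean.copy(), k_m2.copy(), k_n)

    result = _summarize(dataset, model, store, config,
                        k_mean, k_m2, k_n, acc_mean)
    return store, result


def _summarize(dataset, model, store: ChainStore, config: NormConfig,
               k_mean, k_m2, k_n, acc_mean) -> NormalizedResult:
    I, P, N, H, R = model.dims
    if not config.low_memory:
        # full storage: summarize kappa from the stored post-burn-in draws
        kap = np.concatenate([store.combined("kappa_hk"),
                              store.combined("kappa_reg")], axis=2)
        kappa_mean = kap.mean(axis=0)
        kappa_sd = kap.std(axis=0, ddof=1) if kap.shape[0] > 1 \
            else np.zeros(kap.shape[1:])
    else:
        kappa_mean = k_mean
        kappa_sd = np.sqrt(k_m2 / (k_n - 1)) if k_n > 1 else np.zeros_like(k_m2)
    gene_ids = dataset.probe_ids(ProbeClass.HOUSEKEEPING) \
        + dataset.probe_ids(ProbeClass.REGULAR)
    gene_cols = np.hstack([dataset.counts_for(ProbeClass.HOUSEKEEPING),
                           dataset.counts_for(ProbeClass.REGULAR)])
    unreliable = [g for j, g in enumerate(gene_ids)
                  if np.all(gene_cols[:, j] == 0)]

    phi_mean = store.combined("phi").mean(axis=0)
    lam_h = store.combined("lambda_hk").mean(axis=0)
    lam_r = store.combined("lambda_reg").mean(axis=0)
    d_pos = store.combined("d_pos").mean(axis=0)
    d_neg = store.combined("d_neg").mean(axis=0)
    d_rows = [{"probe_id": pid, "class": "positive", "d_mean": d_pos[j]}
              for j, pid in enumerate(dataset.probe_ids(ProbeClass.POSITIVE))]
    d_rows += [{"probe_id": pid, "class": "negative", "d_mean": d_neg[j]}
               for j, pid in enumerate(dataset.probe_ids(ProbeClass.NEGATIVE))]
    var_rows = []
    for p in SCALAR_PARAMS:
        v = store.combined(p)
        var_rows.append({"parameter": p, "mean": float(v.mean()),
                         "median": float(np.median(v)),
                         "sd": float(v.std(ddof=1))})
    mon = [p for p in store.parameters if store.draws[p].ndim == 2]
    diag = psrf_report(store, mon) if store.n_chains >= 2 else GRReport(psrf={})

    # posterior means of a, b from the online accumulators (kept for every
    # sample regardless of storage mode)
    a_mean = acc_mean["a"].copy()
    b_mean = acc_mean["b"].copy()

    return NormalizedResult(
        sample_ids=list(dataset.sample_ids),
        gene_ids=gene_ids,
        kappa_mean=kappa_mean, kappa_sd=kappa_sd,
        phi_mean=phi_mean, a_mean=a_mean, b_mean=b_mean,
        c_mean=float(store.combined("c").mean()),
        d_summary=pd.DataFrame(d_rows),
        variance_summary=pd.DataFrame(var_rows),
        diagnostics=diag,
        unreliable_genes=unreliable,
    )


def run_metanorm(dataset: NCounterDataset, config: NormConfig | None = None
                 ) -> tuple[ChainStore, NormalizedResult]:
    """Normalize one dataset with full chain storage.

    Returns the multi-chain draws and the posterior summaries; the kappa
    posterior means in the result are the normalized log10 expression
    values.
    """
    return _run(dataset, config or NormConfig())


def rolling_run(dataset: NCounterDataset, config: NormConfig | None = None
                ) -> NormalizedResult:
    """Low-memory normalization: identical sweep computations and draw
    sequence to :func:`run_metanorm` at the same seed, but kappa draws
    are folded into online mean/variance accumulators after burn-in
    instead of being stored.  Global parameters remain fully stored for
    diagnostics."""
    config = config or NormConfig(low_memory=True)
    if not config.low_memory:
        config = replace(config, low_memory=True)
    _, result = _run(dataset, config)
    return result


@dataclass
class BiasReport:
    """Per-run and aggregate bias of normalized expression estimates."""

    per_run_bias: np.ndarray
    mean_bias: float
    percent_change: float

    def summary(self) -> str:
        return (f"mean kappa bias {self.mean_bias:+.4f} (log10), "
                f"count-scale change {100 * self.percent_change:+.2f}% "
                f"over {self.per_run_bias.size} runs")


def bias_experiment(sim_config, dims, n_runs: int, config: NormConfig,
                    seed: int) -> BiasReport:
    """Repeatedly simulate a dataset with known latent expression,
    normalize it, and record mean(kappa_hat - kappa_true) over the
    regular genes.  The aggregate report carries the mean log10 bias b
    and the implied count-scale percent change 10**b - 1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    from .synthetic import simulate_ncounter
    root = np.random.SeedSequence(seed)
    biases = np.empty(n_runs)
    for r, ss in enumerate(root.spawn(n_runs)):
        sim_seed = int(ss.generate_state(1)[0] % (2**31))
        dataset, truth = simulate_ncounter(sim_config, dims, sim_seed)
        run_cfg = replace(config, seed=sim_seed + 1)
        _, result = _run(dataset, run_cfg)
        H = truth.kappa_hk.shape[1]
        kappa_hat_reg = result.kappa_mean[:, H:]
        biases[r] = float(np.mean(kappa_hat_reg - truth.kappa_reg))
    mean_bias = float(biases.mean())
    return BiasReport(per_run_bias=biases, mean_bias=mean_bias,
                      percent_change=percent_change(mean_bias))


def export_normalized(result: NormalizedResult, path,
                      sd_path=None, summary_path=None) -> None:
    """Write kappa posterior means (samples x genes CSV), kappa SDs and a
    parameter-summary CSV.  Companion paths default to ``*_sd.csv`` and
    ``*_params.csv`` next to ``path``."""
    path = Path(path)
    sd_path = Path(sd_path) if sd_path else path.with_name(path.stem + "_sd.csv")
    summary_path = Path(summary_path) if summary_path \
        else path.with_name(path.stem + "_params.csv")
    km = result.kappa_frame()
    km.index.name = "sample_id"
    km.to_csv(path)
    ks = pd.DataFrame(result.kappa_sd, index=result.sample_ids,
                      columns=result.gene_ids)
    ks.index.name = "sample_id"
    ks.to_csv(sd_path)
    rows = result.variance_summary.copy()
    extra = pd.DataFrame([
        {"parameter": "c", "mean": result.c_mean, "median": np.nan, "sd": np.nan},
    ])
    pd.concat([rows, extra], ignore_index=True).to_csv(summary_path, index=False)
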