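"""Joint-distribution ("getting it right") validation of both Gibbs
samplers.

Alternating (1) a draw of data given parameters with (2) one
full-conditional sweep of parameters given data is a Markov chain whose
stationary marginal over parameters is exactly the prior.  Comparing the
marginals visited by that chain against direct prior draws therefore
checks every derived full conditional at once: any error in a
conditional shifts some marginal away from its prior.

Both tests use tiny instances, moderately informative inverse-gamma
priors for numerical tameness, explicit wide safe ranges, and fixed
seeds.  Because the successive-conditional chain is autocorrelated,
agreement is judged Geweke-style: z-scores for the first two moments of
each monitored marginal, with the chain's standard error inflated by its
integrated autocorrelation time.  An injected error in any conditional
(for example a wrong inverse-gamma shape) moves these z-scores far
outside the acceptance band.
"""

import numpy as np
import pytest
from scipy import stats

from metanorm import MetaStudyCollection, NormConfig, PriorSpec, simulate_ncounter
from metanorm.constraints import constraint_basis
from metanorm.datamodel import default_positive_levels
from metanorm.diagnostics import autocorr
from metanorm.meta import MetaConfig, _MetaState, meta_sweep
from metanorm.normalize import _NormModel, _NormState, norm_sweep
from metanorm.synthetic import NormSimConfig

Z_BOUND = 4.5  # per-moment acceptance band; seeds are fixed


def _uniform_on_constrained_box(rng, Q, lo, hi):
    """Rejection-sample a vector uniform on {Qu : lo <= Qu <= hi}."""
    rho = np.sqrt(np.sum(np.maximum(lo**2, hi**2)))
    for _ in range(100000):
        u = rng.uniform(-rho, rho, Q.shape[1])
        v = Q @ u
        if np.all(v >= lo) and np.all(v <= hi):
            return v
    raise RuntimeError("rejection sampling failed")


def _iact(x, cap=400):
    """Integrated autocorrelation time via an initial positive-sequence
    window (sum lags until the autocorrelation drops below 0.01)."""
    ac = autocorr(x, min(cap, x.size // 3))
    s = 1.0
    for k in range(1, ac.size):
        if ac[k] < 0.01:
            break
        s += 2 * ac[k]
    return s


def assert_marginals_match(chain, ref, names, log_params=()):
    """Geweke z-scores for mean and second moment of every marginal."""
    failures = []
    for j, name in enumerate(names):
        c = np.asarray(chain[:, j], float)
        r = np.asarray(ref[:, j], float)
        if name in log_params:
            c, r = np.log(c), np.log(r)
        for moment, f in (("mean", lambda v: v), ("m2", lambda v: v**2)):
            fc, fr = f(c), f(r)
            se = np.sqrt(fc.var() * _iact(fc) / fc.size + fr.var() / fr.size)
            z = (fc.mean() - fr.mean()) / se
            if abs(z) > Z_BOUND:
                failures.append(f"{name}/{moment}: z = {z:.2f}")
    assert not failures, "; ".join(failures)


# ---------------------------------------------------------------------------
# meta-analysis sampler
# ---------------------------------------------------------------------------

class TestMetaSamplerPreservesPrior:
    K, N_PER = 2, 3
    EPS = 3.0
    IW_DF, IW_SCALE = 5.0, 1.0
    A_RANGE, B_RANGE = (1.0, 3.5), (0.4, 1.6)
    T_HW = 3.0
    MONITORED = ("mu_alpha", "mu_beta", "sigma_alpha2", "tau2", "t0", "s00",
                 "alpha0", "sigma_k00", "a00", "sigma_jk00")
    LOG_PARAMS = ("sigma_alpha2", "tau2", "sigma_k00", "sigma_jk00")

    def _config(self, x):
        return MetaConfig(
            n_chains=1, n_draws=10, burn_in=1, ig_epsilon=self.EPS,
            iw_df=self.IW_DF, iw_scale=self.IW_SCALE * np.eye(2),
            mu_alpha_range=self.A_RANGE, mu_beta_range=self.B_RANGE,
            t_ranges=np.tile([-self.T_HW, self.T_HW], (x.size, 1)))

    def _prior_draw(self, rng, x, Q):
        K, n = self.K, self.N_PER
        J = x.size
        mu_alpha = rng.uniform(*self.A_RANGE)
        mu_beta = rng.uniform(*self.B_RANGE)
        sigma_alpha2 = float(self.EPS / rng.gamma(self.EPS))
        sigma_beta2 = float(self.EPS / rng.gamma(self.EPS))
        tau2 = float(self.EPS / rng.gamma(self.EPS))
        sigma_jk2 = self.EPS / rng.gamma(self.EPS, size=(K, J))
        sigma_k = stats.invwishart.rvs(self.IW_DF, self.IW_SCALE * np.eye(2),
                                       size=K, random_state=rng).reshape(K, 2, 2)
        alpha = rng.normal(mu_alpha, np.sqrt(sigma_alpha2), K)
        beta = rng.normal(mu_beta, np.sqrt(sigma_beta2), K)
        lo, hi = np.full(J, -self.T_HW), np.full(J, self.T_HW)
        t = _uniform_on_constrained_box(rng, Q, lo, hi)
        s = t[None, :] + rng.normal(0, np.sqrt(tau2), (K, Q.shape[1])) @ Q.T
        a, b = [None] * K, [None] * K
        for k in range(K):
            w = rng.multivariate_normal([alpha[k], beta[k]], sigma_k[k], size=n)
            a[k], b[k] = w[:, 0].copy(), w[:, 1].copy()
        return _MetaState(a=a, b=b, sigma_k=sigma_k, alpha=alpha, beta=beta,
                          mu_alpha=mu_alpha, mu_beta=mu_beta,
                          sigma_alpha2=sigma_alpha2, sigma_beta2=sigma_beta2,
                          tau2=tau2, sigma_jk2=sigma_jk2, s=s, t=t)

    def _draw_data(self, rng, state, x):
        studies = []
        for k in range(self.K):
            mean = state.a[k][:, None] + np.outer(state.b[k], x) \
                + state.s[k][None, :]
            logY = rng.normal(mean, np.sqrt(state.sigma_jk2[k])[None, :])
            studies.append((f"s{k}", logY))
        return MetaStudyCollection(studies=studies, x_levels=x)

    @staticmethod
    def _extract(state):
        return (state.mu_alpha, state.mu_beta, state.sigma_alpha2, state.tau2,
                state.t[0], state.s[0, 0], state.alpha[0],
                state.sigma_k[0, 0, 0], state.a[0][0], state.sigma_jk2[0, 0])

    def test_successive_conditional_marginals_match_prior(self):
        x = default_positive_levels()
        Q = constraint_basis(x.size, x)
        cfg = self._config(x)
        rng = np.random.default_rng(2024)

        state = self._prior_draw(rng, x, Q)
        chain = np.empty((30000, len(self.MONITORED)))
        for it in range(chain.shape[0]):
            col = self._draw_data(rng, state, x)
            meta_sweep(state, col, cfg, rng, Q, self.A_RANGE, self.B_RANGE,
                       cfg.t_ranges)
            chain[it] = self._extract(state)

        rng_ref = np.random.default_rng(77)
        ref = np.array([self._extract(self._prior_draw(rng_ref, x, Q))
                        for _ in range(12000)])
        assert_marginals_match(chain, ref, self.MONITORED, self.LOG_PARAMS)


# ---------------------------------------------------------------------------
# normalization sampler
# ---------------------------------------------------------------------------

class TestNormalizationSamplerPreservesPrior:
    DIMS = (3, 6, 2, 2, 2)  # I, P, N, H, R
    EPS = 3.0
    C_RANGE = (-2.5, -0.5)
    PHI_HW = 2.0
    LAM_RANGE = (0.5, 2.5)
    PRIORS = {"mu_a": (2.3, 0.04), "mu_b": (0.95, 0.01)}
    MONITORED = ("mu_a", "mu_b", "sigma_e2", "sigma_d2", "sigma_kappa2", "c",
                 "phi0", "d_pos0", "d_neg0", "kappa_r00", "lam_r0", "a0")
    LOG_PARAMS = ("sigma_e2", "sigma_d2", "sigma_kappa2")

    def _config(self, constrained):
        I, P, N, H, R = self.DIMS
        return NormConfig(
            n_chains=1, n_draws=10, burn_in=1,
            priors=PriorSpec(mu_a_prior=self.PRIORS["mu_a"],
                             mu_b_prior=self.PRIORS["mu_b"],
                             ig_epsilon=self.EPS),
            enforce_d_constraints=constrained, fixed_updates=False,
            c_range=self.C_RANGE,
            phi_ranges=np.tile([-self.PHI_HW, self.PHI_HW], (I, 1)),
            lambda_hk_ranges=np.tile(self.LAM_RANGE, (H, 1)),
            lambda_reg_ranges=np.tile(self.LAM_RANGE, (R, 1)))

    def _model(self, config):
        ds, _ = simulate_ncounter(NormSimConfig(), self.DIMS, seed=1)
        return _NormModel(ds, config)

    def _prior_draw(self, rng, model, constrained):
        I, P, N, H, R = self.DIMS
        def ig(size=None):
            return self.EPS / rng.gamma(self.EPS, size=size)
        mu_a = rng.normal(self.PRIORS["mu_a"][0],
                          np.sqrt(self.PRIORS["mu_a"][1]))
        mu_b = rng.normal(self.PRIORS["mu_b"][0],
                          np.sqrt(self.PRIORS["mu_b"][1]))
        s_a2, s_b2, s_e2, s_n2 = ig(), ig(), ig(), ig()
        s_d2, s_dn2, s_k2, s_ks2 = ig(), ig(), ig(), ig()
        a = rng.normal(mu_a, np.sqrt(s_a2), I)
        b = rng.normal(mu_b, np.sqrt(s_b2), I)
        c = rng.uniform(*self.C_RANGE)
        phi = _uniform_on_constrained_box(
            rng, model.Q_phi, np.full(I, -self.PHI_HW), np.full(I, self.PHI_HW))
        lam_h = rng.uniform(*self.LAM_RANGE, H)
        lam_r = rng.uniform(*self.LAM_RANGE, R)
        kappa_h = rng.normal(lam_h[None, :], np.sqrt(s_ks2), (I, H))
        kappa_r = rng.normal(lam_r[None, :], np.sqrt(s_k2), (I, R))
        d_pos = rng.normal(0, np.sqrt(s_d2), P)
        d_neg = rng.normal(0, np.sqrt(s_dn2), N)
        if constrained:
            # isotropic normal restricted to the subspace == projection
            d_pos = model.Q_pos @ (model.Q_pos.T @ d_pos)
            d_neg = model.Q_neg @ (model.Q_neg.T @ d_neg)
        return _NormState(
            a=a, b=b, c=c, phi=phi, kappa_h=kappa_h, kappa_r=kappa_r,
            lam_h=lam_h, lam_r=lam_r, d_pos=d_pos, d_neg=d_neg,
            d_hk=rng.normal(0, np.sqrt(s_d2), H),
            d_reg=rng.normal(0, np.sqrt(s_d2), R),
            mu_a=mu_a, mu_b=mu_b, sigma_a2=s_a2, sigma_b2=s_b2,
            sigma_e2=s_e2, sigma_n2=s_n2, sigma_d2=s_d2, sigma_d_neg2=s_dn2,
            sigma_kappa2=s_k2, sigma_kappa_star2=s_ks2)

    def _draw_data(self, rng, state, model):
        se, sn = np.sqrt(state.sigma_e2), np.sqrt(state.sigma_n2)
        model.Yp = rng.normal(state.a[:, None] + np.outer(state.b, model.x)
                              + state.d_pos[None, :], se)
        model.Yn = rng.normal(state.a[:, None] + state.b[:, None] * state.c
                              + state.d_neg[None, :], sn)
        model.Yh = rng.normal(
            state.a[:, None]
            + state.b[:, None] * (state.phi[:, None] + state.kappa_h)
            + state.d_hk[None, :], se)
        model.Yr = rng.normal(
            state.a[:, None]
            + state.b[:, None] * (state.phi[:, None] + state.kappa_r)
            + state.d_reg[None, :], se)

    @staticmethod
    def _extract(state):
        return (state.mu_a, state.mu_b, state.sigma_e2, state.sigma_d2,
                state.sigma_kappa2, state.c, state.phi[0], state.d_pos[0],
                state.d_neg[0], state.kappa_r[0, 0], state.lam_r[0],
                state.a[0])

    @pytest.mark.parametrize("constrained", [True, False],
                             ids=["constraints_on", "constraints_off"])
    def test_successive_conditional_marginals_match_prior(self, constrained):
        config = self._config(constrained)
        model = self._model(config)
        rng = np.random.default_rng(555)

        state = self._prior_draw(rng, model, constrained)
        chain = np.empty((20000, len(self.MONITORED)))
        for it in range(chain.shape[0]):
            self._draw_data(rng, state, model)
            norm_sweep(state, model, config, rng)
            chain[it] = self._extract(state)

        rng_ref = np.random.default_rng(333)
        ref = np.array([
            self._extract(self._prior_draw(rng_ref, model, constrained))
            for _ in range(12000)])
        assert_marginals_match(chain, ref, self.MONITORED, self.LOG_PARAMS)

    def test_constrained_draws_satisfy_constraints_every_sweep(self):
        config = self._config(True)
        model = self._model(config)
        rng = np.random.default_rng(11)
        state = self._prior_draw(rng, model, True)
        x = model.x
        for _ in range(200):
            self._draw_data(rng, state, model)
            norm_sweep(state, model, config, rng)
            assert abs(state.d_pos.sum()) <= 1e-8
            assert abs((state.d_pos * x).sum()) <= 1e-8
            assert abs(state.d_neg.sum()) <= 1e-8
            assert abs(state.phi.sum()) <= 1e-8
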