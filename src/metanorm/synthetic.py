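"""Synthetic nCounter data with known ground truth.

Two generators mirror the two hierarchical models in the package:

* :func:`simulate_ncounter` draws a single-study dataset from the
  random-coefficient normalization model (per-sample intercepts/slopes,
  probe deviations, sample degradation phi, latent expression kappa) and
  emits integer counts plus the full latent truth.
* :func:`simulate_meta` draws a multi-study collection of positive-probe
  log counts from the meta-analysis model (study-level coefficient means
  and covariances, constrained probe-effect residuals).

Defaults emulate a high-quality FFPE lung-cancer study with 28 samples
and the standard six-probe positive-control ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constraints import constraint_basis, constraint_project
from .datamodel import (
    DEFAULT_PSEUDOCOUNT,
    MetaStudyCollection,
    NCounterDataset,
    ProbeAnnotation,
    ProbeClass,
    default_positive_levels,
)

__all__ = [
    "NormSimConfig",
    "NormTruth",
    "MetaSimConfig",
    "MetaTruth",
    "simulate_ncounter",
    "simulate_meta",
    "dataset4_like_config",
]


@dataclass
class NormSimConfig:
    """Hyperparameters (and optional fixed latents) for single-study
    generation.

    Variances are on the log10-count scale.  Setting a variance to zero
    produces the corresponding noiseless limit; negative variances are
    rejected.  Any of the ``fixed_*`` fields pins the latent instead of
    drawing it, which the tests use for analytic checks.
    """

    mu_a: float = 2.357
    mu_b: float = 0.952
    c: float = -1.5
    sigma_a2: float = 0.01
    sigma_b2: float = 0.001
    sigma_e2: float = 0.004
    sigma_n2: float = 0.02
    sigma_d2: float = 0.004
    sigma_d_neg2: float = 0.01
    sigma_kappa2: float = 0.05
    sigma_kappa_star2: float = 0.02
    sigma_phi2: float = 0.01
    lambda_reg_range: tuple[float, float] = (0.0, 3.0)
    lambda_hk_range: tuple[float, float] = (1.0, 3.0)
    constrain_d: bool = True
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    positive_levels_fM: tuple[float, ...] = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
    fixed_a: np.ndarray | float | None = None
    fixed_b: np.ndarray | float | None = None
    fixed_phi: np.ndarray | float | None = None
    fixed_d: float | None = None
    fixed_lambda_reg: np.ndarray | float | None = None
    fixed_lambda_hk: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_a2", "sigma_b2", "sigma_e2", "sigma_n2",
                     "sigma_d2", "sigma_d_neg2", "sigma_kappa2",
                     "sigma_kappa_star2", "sigma_phi2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class NormTruth:
    """Realized latent values behind one simulated dataset."""

    a: np.ndarray
    b: np.ndarray
    c: float
    phi: np.ndarray
    kappa_hk: np.ndarray
    kappa_reg: np.ndarray
    lambda_hk: np.ndarray
    lambda_reg: np.ndarray
    d_pos: np.ndarray
    d_neg: np.ndarray
    d_hk: np.ndarray
    d_reg: np.ndarray
    mu_a: float
    mu_b: float
    variances: dict[str, float]
    y_log: np.ndarray  # noiseless+noise log10 scale observations, I x (P+N+H+R)

    def validate(self, x_pos: np.ndarray, atol: float = 1e-10,
                 constrained: bool = True) -> None:
        assert abs(self.phi.sum()) <= atol * max(1, self.phi.size)
        if constrained:
            assert abs(self.d_pos.sum()) <= atol
            assert abs((self.d_pos * x_pos).sum()) <= atol
            assert abs(self.d_neg.sum()) <= atol


def _draw_or_fix(rng, fixed, mean, sd, size):
    if fixed is not None:
        return np.broadcast_to(np.asarray(fixed, dtype=float), size).copy()
    return rng.normal(mean, sd, size=size)


def dataset4_like_config(**overrides) -> tuple[NormSimConfig, tuple[int, int, int, int, int]]:
    """Config and dims emulating the high-quality 28-sample lung FFPE study
    (I=28, P=6, N=8, H=7, R=83) used for the bias experiments."""
    return NormSimConfig(**overrides), (28, 6, 8, 7, 83)


def simulate_ncounter(config: NormSimConfig,
                      dims: tuple[int, int, int, int, int],
                      seed: int) -> tuple[NCounterDataset, NormTruth]:
    """Draw one single-study dataset from the normalization model.

    Log-scale observations are assembled per probe class (positive,
    negative, housekeeping, regular) and converted to integer counts via
    round(10**Y - pseudocount) clipped at zero.  Probe-deviation vectors
    are orthogonally projected onto their identifiability subspaces when
    ``config.constrain_d`` is set, preserving Gaussianity within the
    subspace.
    """
    I, P, N, H, R = dims
    if I < 2:
        raise ValueError("need at least 2 samples")
    if P != len(config.positive_levels_fM):
        raise ValueError("dims P inconsistent with configured positive levels")
    rng = np.random.default_rng(seed)
    x_pos = np.log10(np.asarray(config.positive_levels_fM, dtype=float))

    a = _draw_or_fix(rng, config.fixed_a, config.mu_a, np.sqrt(config.sigma_a2), I)
    b = _draw_or_fix(rng, config.fixed_b, config.mu_b, np.sqrt(config.sigma_b2), I)

    if config.fixed_phi is not None:
        phi = np.broadcast_to(np.asarray(config.fixed_phi, dtype=float), I).copy()
    else:
        phi = rng.normal(0.0, np.sqrt(config.sigma_phi2), I)
        phi -= phi.mean()  # degradation levels sum to zero by construction

    if config.fixed_lambda_reg is not None:
        lam_r = np.broadcast_to(np.asarray(config.fixed_lambda_reg, float), R).copy()
    else:
        lam_r = rng.uniform(*config.lambda_reg_range, size=R)
    if config.fixed_lambda_hk is not None:
        lam_h = np.broadcast_to(np.asarray(config.fixed_lambda_hk, float), H).copy()
    else:
        lam_h = rng.uniform(*config.lambda_hk_range, size=H)

    kappa_r = rng.normal(lam_r, np.sqrt(config.sigma_kappa2), size=(I, R))
    kappa_h = rng.normal(lam_h, np.sqrt(config.sigma_kappa_star2), size=(I, H))

    if config.fixed_d is not None:
        d_pos = np.full(P, float(config.fixed_d))
        d_neg = np.full(N, float(config.fixed_d))
        d_hk = np.full(H, float(config.fixed_d))
        d_reg = np.full(R, float(config.fixed_d))
    else:
        sd_d = np.sqrt(config.sigma_d2)
        d_pos = rng.normal(0.0, sd_d, P)
        d_hk = rng.normal(0.0, sd_d, H)
        d_reg = rng.normal(0.0, sd_d, R)
        d_neg = rng.normal(0.0, np.sqrt(config.sigma_d_neg2), N)
        if config.constrain_d:
            d_pos = constraint_project(d_pos, x_pos)
            d_neg = constraint_project(d_neg)

    se = np.sqrt(config.sigma_e2)
    sn = np.sqrt(config.sigma_n2)
    y_pos = a[:, None] + b[:, None] * x_pos[None, :] + d_pos[None, :] \
        + rng.normal(0.0, se, (I, P))
    y_neg = a[:, None] + b[:, None] * config.c + d_neg[None, :] \
        + rng.normal(0.0, sn, (I, N))
    y_hk = a[:, None] + b[:, None] * (phi[:, None] + kappa_h) + d_hk[None, :] \
        + rng.normal(0.0, se, (I, H))
    y_reg = a[:, None] + b[:, None] * (phi[:, None] + kappa_r) + d_reg[None, :] \
        + rng.normal(0.0, se, (I, R))
    y_log = np.hstack([y_pos, y_neg, y_hk, y_reg])

    counts = np.maximum(np.round(10.0 ** y_log - config.pseudocount), 0).astype(np.int64)

    annotation = (
        [ProbeAnnotation(f"POS_{chr(65 + p)}", ProbeClass.POSITIVE,
                         config.positive_levels_fM[p]) for p in range(P)]
        + [ProbeAnnotation(f"NEG_{n + 1}", ProbeClass.NEGATIVE) for n in range(N)]
        + [ProbeAnnotation(f"HK_{h + 1}", ProbeClass.HOUSEKEEPING) for h in range(H)]
        + [ProbeAnnotation(f"GENE_{r + 1}", ProbeClass.REGULAR) for r in range(R)]
    )
    dataset = NCounterDataset(
        counts=counts,
        sample_ids=[f"S{i + 1}" for i in range(I)],
        annotation=annotation,
        pseudocount=config.pseudocount,
    )
    truth = NormTruth(
        a=a, b=b, c=config.c, phi=phi,
        kappa_hk=kappa_h, kappa_reg=kappa_r,
        lambda_hk=lam_h, lambda_reg=lam_r,
        d_pos=d_pos, d_neg=d_neg, d_hk=d_hk, d_reg=d_reg,
        mu_a=config.mu_a, mu_b=config.mu_b,
        variances={
            "sigma_a2": config.sigma_a2, "sigma_b2": config.sigma_b2,
            "sigma_e2": config.sigma_e2, "sigma_n2": config.sigma_n2,
            "sigma_d2": config.sigma_d2, "sigma_d_neg2": config.sigma_d_neg2,
            "sigma_kappa2": config.sigma_kappa2,
            "sigma_kappa_star2": config.sigma_kappa_star2,
        },
        y_log=y_log,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# multi-study meta-analysis generator
# ---------------------------------------------------------------------------

@dataclass
class MetaSimConfig:
    """Hyperparameters for multi-study positive-probe generation.

    Study coefficient means alpha_k, beta_k are drawn around the global
    means; within-study coefficient pairs share a study-specific 2x2
    covariance built from ``coef_scales`` and a correlation drawn
    uniformly from ``corr_range`` (or supplied explicitly via
    ``sigma_k``).  Probe effects s_jk and their means t_j live in the
    4-dimensional constraint subspace.
    """

    mu_alpha: float = 2.357
    mu_beta: float = 0.952
    sigma_alpha2: float = 0.047
    sigma_beta2: float = 0.003
    coef_scales: tuple[float, float] = (0.12, 0.04)  # SDs of a, b within study
    corr_range: tuple[float, float] = (-0.6, 0.6)
    sigma_k: list[np.ndarray] | None = None
    t_scale: float = 0.02
    fixed_t: np.ndarray | None = None
    tau2: float = 1e-4
    resid_var_range: tuple[float, float] = (0.001, 0.008)
    x_levels: np.ndarray = field(default_factory=default_positive_levels)


@dataclass
class MetaTruth:
    """Realized latents behind one simulated multi-study collection.

    ``s_jk`` and ``sigma_jk2`` are stored study-major with shape (K, 6).
    """

    alpha: np.ndarray
    beta: np.ndarray
    sigma_k: np.ndarray        # K x 2 x 2
    mu_alpha: float
    mu_beta: float
    sigma_alpha2: float
    sigma_beta2: float
    s_jk: np.ndarray           # K x 6
    t: np.ndarray              # 6
    tau2: float
    sigma_jk2: np.ndarray      # K x 6
    a_ik: list[np.ndarray]
    b_ik: list[np.ndarray]


def simulate_meta(config: MetaSimConfig, K: int, I_k: list[int] | int,
                  seed: int) -> tuple[MetaStudyCollection, MetaTruth]:
    """Draw a K-study collection of positive-probe log counts.

    Coefficient pairs (a_ik, b_ik) come from the study-level bivariate
    normal; residual probe effects s_jk are drawn around the global
    pattern t and projected into the subspace where they sum to zero both
    plainly and against the design vector.
    """
    if K < 2:
        raise ValueError("need at least 2 studies")
    sizes = [I_k] * K if isinstance(I_k, int) else list(I_k)
    if len(sizes) != K or any(s < 2 for s in sizes):
        raise ValueError("each study needs at least 2 samples")
    rng = np.random.default_rng(seed)
    x = np.asarray(config.x_levels, dtype=float)
    J = x.size
    Q = constraint_basis(J, x)

    alpha = rng.normal(config.mu_alpha, np.sqrt(config.sigma_alpha2), K)
    beta = rng.normal(config.mu_beta, np.sqrt(config.sigma_beta2), K)

    if config.sigma_k is not None:
        sigma_k = np.asarray(config.sigma_k, dtype=float)
        if sigma_k.shape != (K, 2, 2):
            raise ValueError("sigma_k must be K x 2 x 2")
    else:
        sa, sb = config.coef_scales
        rho = rng.uniform(*config.corr_range, size=K)
        sigma_k = np.empty((K, 2, 2))
        sigma_k[:, 0, 0] = sa**2
        sigma_k[:, 1, 1] = sb**2
        sigma_k[:, 0, 1] = sigma_k[:, 1, 0] = rho * sa * sb
    for k in range(K):
        if np.linalg.eigvalsh(sigma_k[k]).min() <= 0:
            raise ValueError(f"sigma_k[{k}] is not positive definite")

    if config.fixed_t is not None:
        t = constraint_project(np.asarray(config.fixed_t, float), x)
    else:
        t = constraint_project(rng.normal(0.0, config.t_scale, J), x)

    sigma_jk2 = rng.uniform(*config.resid_var_range, size=(K, J))
    s_jk = t[None, :] + rng.normal(0.0, np.sqrt(config.tau2), (K, Q.shape[1])) @ Q.T

    studies, a_list, b_list = [], [], []
    for k, n in enumerate(sizes):
        coefs = rng.multivariate_normal([alpha[k], beta[k]], sigma_k[k], size=n,
                                        method="cholesky")
        a_ik, b_ik = coefs[:, 0], coefs[:, 1]
        delta = rng.normal(0.0, np.sqrt(sigma_jk2[k])[None, :], size=(n, J))
        logY = a_ik[:, None] + b_ik[:, None] * x[None, :] + s_jk[k][None, :] + delta
        studies.append((f"study_{k + 1}", logY))
        a_list.append(a_ik)
        b_list.append(b_ik)

    collection = MetaStudyCollection(studies=studies, x_levels=x)
    truth = MetaTruth(
        alpha=alpha, beta=beta, sigma_k=sigma_k,
        mu_alpha=config.mu_alpha, mu_beta=config.mu_beta,
        sigma_alpha2=config.sigma_alpha2, sigma_beta2=config.sigma_beta2,
        s_jk=s_jk, t=t, tau2=config.tau2, sigma_jk2=sigma_jk2,
        a_ik=a_list, b_ik=b_list,
    )
    return collection, truth
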