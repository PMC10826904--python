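"""MCMC chain storage and convergence diagnostics.

Implements the classic Gelman-Rubin potential scale reduction factor
(PSRF) with its F-quantile 95% upper bound, sample autocorrelation, and a
thinning recommendation rule (smallest lag at which all monitored
parameters fall below an autocorrelation threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChainStore",
    "GRReport",
    "gelman_rubin",
    "psrf_report",
    "autocorr",
    "recommend_thinning",
]


@dataclass
class ChainStore:
    """Multi-chain MCMC draws keyed by parameter name.

    ``draws[name]`` has shape (n_chains, n_draws) for scalar parameters or
    (n_chains, n_draws, ...) for vector-valued ones.  ``rolling`` holds
    online posterior summaries (mean, M2, count) for parameters that were
    accumulated instead of stored (low-memory mode).
    """

    draws: dict[str, np.ndarray]
    n_chains: int
    n_draws: int
    burn_in: int
    thin: int = 1
    seeds: list[int] = field(default_factory=list)
    rolling: dict[str, tuple[np.ndarray, np.ndarray, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_draws):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_draws")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        for name, arr in self.draws.items():
            arr = np.asarray(arr)
            if arr.shape[:2] != (self.n_chains, self.n_draws):
                raise ValueError(
                    f"parameter {name!r}: draws shape {arr.shape} inconsistent "
                    f"with ({self.n_chains}, {self.n_draws}, ...)"
                )
            self.draws[name] = arr

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def post_burnin(self, name: str, burn_in: int | None = None,
                    thin: int | None = None) -> np.ndarray:
        """Draws after burn-in removal and thinning, per chain."""
        b = self.burn_in if burn_in is None else burn_in
        t = self.thin if thin is None else thin
        if b >= self.n_draws:
            raise ValueError("burn_in must be smaller than the chain length")
        return self.draws[name][:, b::t]

    def combined(self, name: str, **kw) -> np.ndarray:
        """Post-burn-in draws pooled across chains (first axis flattened)."""
        arr = self.post_burnin(name, **kw)
        return arr.reshape(-1, *arr.shape[2:])


@dataclass
class GRReport:
    """Gelman-Rubin PSRF per parameter: point estimate and 95% upper bound.

    Raw values are preserved; ``rounded`` applies the 2-decimal reporting
    convention.
    """

    psrf: dict[str, tuple[float, float]]
    degenerate: dict[str, bool] = field(default_factory=dict)

    def rounded(self) -> dict[str, tuple[float, float]]:
        return {k: (round(p, 2), round(u, 2)) for k, (p, u) in self.psrf.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": k, "psrf": p, "psrf_upper95": u,
             "degenerate": self.degenerate.get(k, False)}
            for k, (p, u) in self.psrf.items()
        ]
        return pd.DataFrame(rows)


def gelman_rubin(chains: np.ndarray, rank_normalize: bool = False,
                 split: bool = False) -> tuple[float, float]:
    """Classic Gelman-Rubin PSRF for one scalar parameter.

    ``chains`` is (m, n) of post-burn-in draws.  With W the mean
    within-chain variance and B/n the variance of chain means,
    Vhat = (n-1)/n * W + B/n and PSRF = sqrt(Vhat / W).  The 95% upper
    bound scales the between-chain term by an F quantile with
    (m-1, 2*W^2/var(s_j^2)) degrees of freedom.

    All-constant chains are degenerate and reported as (1.0, 1.0).
    Optional flags give the split-chain and rank-normalized variants.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains of scalar draws")
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half:2 * half]])
    if rank_normalize:
        flat = chains.ravel()
        ranks = stats.rankdata(flat).reshape(chains.shape)
        chains = stats.norm.ppf((ranks - 0.375) / (flat.size + 0.25))
    m, n = chains.shape
    if n < 3:
        raise ValueError("need chains of length >= 3")
    s2 = chains.var(axis=1, ddof=1)
    W = s2.mean()
    means = chains.mean(axis=1)
    B_over_n = means.var(ddof=1)
    if W <= 0:
        return (1.0, 1.0)
    vhat = (n - 1) / n * W + B_over_n
    point = float(np.sqrt(vhat / W))
    var_s2 = s2.var(ddof=1) if m > 1 else 0.0
    if var_s2 > 0:
        df_w = 2 * W**2 / var_s2
        fq = stats.f.ppf(0.975, m - 1, df_w)
    else:
        fq = 1.0
    upper = float(np.sqrt((n - 1) / n + fq * B_over_n / W))
    return (point, max(point, upper))


def psrf_report(store: ChainStore, parameters: list[str] | None = None,
                **kw) -> GRReport:
    """PSRF point/upper-95 for every scalar monitored parameter of a store."""
    params = parameters if parameters is not None else [
        p for p in store.parameters if store.draws[p].ndim == 2
    ]
    out, degen = {}, {}
    for p in params:
        arr = store.post_burnin(p)
        degenerate = np.allclose(arr.var(axis=1), 0.0)
        out[p] = gelman_rubin(arr, **kw) if not degenerate else (1.0, 1.0)
        degen[p] = bool(degenerate)
    return GRReport(psrf=out, degenerate=degen)


def autocorr(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag.

    Uses the lag-adjusted denominator (n - lag), so a perfectly
    alternating sequence has lag-1 autocorrelation exactly -1.  A constant
    chain returns zeros (flagged by the caller via variance checks).
    """
    x = np.asarray(chain, dtype=float).ravel()
    n = x.size
    if n <= max_lag + 1:
        raise ValueError("chain too short for requested max_lag")
    x = x - x.mean()
    c0 = np.dot(x, x) / n
    if c0 == 0:
        return np.zeros(max_lag + 1)
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for lag in range(1, max_lag + 1):
        out[lag] = np.dot(x[:-lag], x[lag:]) / (n - lag) / c0
    return out


def recommend_thinning(store: ChainStore | dict[str, np.ndarray],
                       threshold: float = 0.05, max_thin: int = 50) -> int:
    """Smallest thinning factor t with |autocorrelation at lag t| below
    ``threshold`` for every monitored scalar parameter and chain.

    Caps at ``max_thin`` with a warning when autocorrelation persists.
    """
    if isinstance(store, ChainStore):
        series = {p: store.post_burnin(p)
                  for p in store.parameters if store.draws[p].ndim == 2}
    else:
        series = {k: np.atleast_2d(np.asarray(v, dtype=float))
                  for k, v in store.items()}
    acfs = []
    for arr in series.values():
        for ch in arr:
            if np.var(ch) == 0:
                continue
            acfs.append(autocorr(ch, min(max_thin, ch.size - 2)))
    if not acfs:
        return 1
    for t in range(1, max_thin + 1):
        if all(a.size > t and abs(a[t]) < threshold for a in acfs):
            return t
    warnings.warn(
        f"autocorrelation above {threshold} persists beyond lag {max_thin}; "
        f"capping thinning factor at {max_thin}", stacklevel=2)
    return max_thin
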