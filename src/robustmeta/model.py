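"""Bayesian bias-adjusted random effects model for binary outcomes.

Model, for study i = 1..K with arms j = 1 (control), 2 (treatment):

    r_ij | p_ij        ~ Binomial(N_ij, p_ij)
    logit(p_i1) = beta_i
    logit(p_i2) = beta_i + delta_i
    delta_i | mu, s2   ~ Normal(mu, s2 / q_i)
    beta_i ~ Normal(mu_beta, sigma_beta^2)
    mu     ~ Normal(mu_mu, sigma_mu^2)
    s2     ~ InvGamma(alpha, lam)        # s2 = sigma_theta^2

The study quality q_i in (0, 1] inflates study i's effect variance from
the between-study variance s2 to s2 + sigma_phi_i^2 = s2 / q_i, where
sigma_phi_i^2 is the variance of an additive study-specific error
(bias).  q_i = 1 is the unadjusted random effects model; the random
effect and error are marginalized analytically and never sampled.

Sampling is Metropolis-within-Gibbs: mu and s2 have exact conjugate
full conditionals (normal and inverse-gamma); each beta_i and delta_i
is updated by an adaptive Gaussian random walk targeting 0.44
acceptance, with adaptation frozen after burn-in.  Chains are run
vectorized; draws are reproducible given (seed, q).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .errors import DataValidationError
from .studies import StudyTable

__all__ = [
    "HyperParams",
    "McmcConfig",
    "ModelState",
    "PosteriorSample",
    "EffectSummary",
    "log_unnormalized_posterior",
    "sample_posterior",
    "summarize",
    "split_rhat",
]


@dataclass(frozen=True)
class HyperParams:
    """Prior hyperparameters.

    Defaults are weakly informative: Normal(0, 10^2) on each control
    log-odds beta_i and on the overall effect mu, InvGamma(0.01, 0.01)
    on the between-study variance.
    """

    mu_beta: float = 0.0
    sigma_beta: float = 10.0
    mu_mu: float = 0.0
    sigma_mu: float = 10.0
    alpha: float = 0.01
    lam: float = 0.01

    def __post_init__(self) -> None:
        if min(self.sigma_beta, self.sigma_mu, self.alpha, self.lam) <= 0:
            raise DataValidationError(
                "sigma_beta, sigma_mu, alpha and lam must all be > 0"
            )

    @classmethod
    def from_dict(cls, spec: dict) -> "HyperParams":
        return cls(**spec)


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``n_iterations`` counts kept iterations per chain (post burn-in,
    before thinning).  Pooled draw count is
    n_chains * n_iterations // thinning.
    """

    n_chains: int = 4
    n_iterations: int = 10_000
    n_burnin: int = 5_000
    thinning: int = 1
    seed: int = 0
    adapt_batch: int = 50
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_iterations, self.n_burnin, self.thinning) < 1:
            raise DataValidationError("all MCMC counts must be >= 1")

    @classmethod
    def from_dict(cls, spec: dict) -> "McmcConfig":
        return cls(**spec)


@dataclass(frozen=True)
class ModelState:
    """One point in parameter space: (beta_1..K, delta_1..K, mu, s2)."""

    beta: np.ndarray
    delta: np.ndarray
    mu: float
    sigma2_theta: float


@dataclass
class PosteriorSample:
    """MCMC output for one fixed quality vector.

    Arrays keep the per-chain partition (chain, draw[, study]) for
    diagnostics; pooled views flatten the chain axis.
    """

    beta: np.ndarray          # (C, D, K)
    delta: np.ndarray         # (C, D, K)
    mu: np.ndarray            # (C, D)
    sigma2_theta: np.ndarray  # (C, D)
    q: np.ndarray             # (K,)
    accept_beta: np.ndarray   # (K,) mean post-burn-in acceptance rate
    accept_delta: np.ndarray  # (K,)
    rhat_mu: float
    rhat_sigma2: float
    ess_mu: float
    converged: bool           # split-Rhat <= threshold on mu and s2

    @property
    def n_draws(self) -> int:
        return self.mu.size

    def pooled(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def to_frame(self):
        """One row per draw: beta_1..K, delta_1..K, mu, sigma2_theta, chain."""
        import pandas as pd

        C, D, K = self.beta.shape
        cols = {}
        for k in range(K):
            cols[f"beta_{k + 1}"] = self.beta[:, :, k].ravel()
        for k in range(K):
            cols[f"delta_{k + 1}"] = self.delta[:, :, k].ravel()
        cols["mu"] = self.mu.ravel()
        cols["sigma2_theta"] = self.sigma2_theta.ravel()
        cols["chain"] = np.repeat(np.arange(C), D)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class EffectSummary:
    """Posterior summaries of the overall effect and per-study effects."""

    mean_mu: float
    sd_mu: float
    percentiles: dict[float, float]       # level (percent) -> value
    exceedance: float                     # P(mu > t)
    threshold: float
    delta_mean: np.ndarray                # (K,)
    delta_lower: np.ndarray               # (K,) 2.5th percentile
    delta_upper: np.ndarray               # (K,) 97.5th percentile

    def quantity(self, name: str) -> float:
        """Look up a scalar summary by name ('mean_mu', 'exceedance', 'p5', ...)."""
        if name == "mean_mu":
            return self.mean_mu
        if name == "exceedance":
            return self.exceedance
        if name.startswith("p"):
            return self.percentiles[float(name[1:])]
        raise KeyError(name)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def log_unnormalized_posterior(
    state: ModelState,
    data: StudyTable,
    q: Sequence[float],
    hp: HyperParams,
) -> float:
    """Log posterior density up to the model-evidence constant.

    All distribution normalizing constants (binomial coefficients,
    normal and inverse-gamma constants) are included, so values agree
    term by term with scipy's log-densities; only the marginal
    likelihood is dropped.  Returns -inf when sigma2_theta <= 0.
    """
    qv = np.asarray(q, dtype=float)
    beta = np.asarray(state.beta, dtype=float)
    delta = np.asarray(state.delta, dtype=float)
    mu, s2 = float(state.mu), float(state.sigma2_theta)
    r1, n1, r2, n2 = data.counts()
    if not (beta.shape == delta.shape == qv.shape == r1.shape):
        raise DataValidationError("state/q/data dimensions disagree")
    if s2 <= 0.0 or not np.isfinite(s2):
        return -np.inf

    def binom_ll(r, n, x):
        # r * logit_p - n * log(1 + e^x) plus the binomial coefficient
        coef = gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)
        return np.sum(coef + r * x - n * _softplus(x))

    ll = binom_ll(r1, n1, beta) + binom_ll(r2, n2, beta + delta)
    var_d = s2 / qv
    ll += np.sum(
        -0.5 * np.log(2.0 * np.pi * var_d) - 0.5 * (delta - mu) ** 2 / var_d
    )
    ll += np.sum(
        -0.5 * np.log(2.0 * np.pi * hp.sigma_beta**2)
        - 0.5 * (beta - hp.mu_beta) ** 2 / hp.sigma_beta**2
    )
    ll += (
        -0.5 * np.log(2.0 * np.pi * hp.sigma_mu**2)
        - 0.5 * (mu - hp.mu_mu) ** 2 / hp.sigma_mu**2
    )
    ll += (
        hp.alpha * np.log(hp.lam)
        - gammaln(hp.alpha)
        - (hp.alpha + 1.0) * np.log(s2)
        - hp.lam / s2
    )
    return float(ll)


def _rng_for(seed: int, q: np.ndarray) -> np.random.Generator:
    """Deterministic generator keyed by (seed, quality vector).

    The quality vector enters through an integer encoding, so the same
    q reuses the same draws across different grids (common random
    numbers for shared points); different q get independent streams.
    """
    enc = tuple(int(round(x * 1e8)) for x in q)
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=enc)
    return np.random.Generator(np.random.PCG64(ss))


def sample_posterior(
    data: StudyTable,
    q: Sequence[float],
    hp: HyperParams | None = None,
    cfg: McmcConfig | None = None,
    rhat_threshold: float = 1.01,
) -> PosteriorSample:
    """Draw from the posterior of (beta, delta, mu, sigma2_theta) at fixed q.

    mu and sigma2_theta use their exact full conditionals:

        mu  | .  ~ Normal(m, 1/tau),  tau = 1/sigma_mu^2 + sum_i q_i / s2,
                   m = (mu_mu/sigma_mu^2 + sum_i q_i delta_i / s2) / tau
        s2  | .  ~ InvGamma(alpha + K/2, lam + sum_i q_i (delta_i - mu)^2 / 2)

    beta_i and delta_i use adaptive Gaussian random walks (independent
    across studies and chains).  Non-convergence (split-Rhat above
    ``rhat_threshold`` on mu or s2) sets ``converged=False`` on the
    returned sample; it is never silent but also never raises.
    """
    hp = hp or HyperParams()
    cfg = cfg or McmcConfig()
    qv = np.asarray(q, dtype=float)
    if qv.ndim != 1 or qv.shape[0] != data.K:
        raise DataValidationError(f"q must have length K={data.K}")
    if np.any(qv <= 0) or np.any(qv > 1):
        raise DataValidationError("all q_i must lie in (0, 1]")
    r1, n1, r2, n2 = data.counts()
    K, C = data.K, cfg.n_chains
    rng = _rng_for(cfg.seed, qv)

    # initial values: empirical logits with per-chain jitter
    b_emp = np.log((r1 + 0.5) / (n1 - r1 + 0.5))
    d_emp = np.log((r2 + 0.5) / (n2 - r2 + 0.5)) - b_emp
    beta = b_emp + 0.1 * rng.standard_normal((C, K))
    delta = d_emp + 0.1 * rng.standard_normal((C, K))
    mu = delta.mean(axis=1)
    s2 = np.full(C, 0.1) * np.exp(0.3 * rng.standard_normal(C))

    ls_beta = np.full((C, K), np.log(0.5))   # log proposal scales
    ls_delta = np.full((C, K), np.log(0.5))
    prec_mu = 1.0 / hp.sigma_mu**2
    shape_s2 = hp.alpha + 0.5 * K
    qsum = qv.sum()

    n_kept = cfg.n_iterations // cfg.thinning
    out_beta = np.empty((C, n_kept, K))
    out_delta = np.empty((C, n_kept, K))
    out_mu = np.empty((C, n_kept))
    out_s2 = np.empty((C, n_kept))

    acc_b = np.zeros((C, K))
    acc_d = np.zeros((C, K))
    batch_b = np.zeros((C, K))
    batch_d = np.zeros((C, K))

    total = cfg.n_burnin + cfg.n_iterations
    kept = 0
    sp_b = _softplus(beta)
    sp_bd = _softplus(beta + delta)
    for it in range(total):
        adapting = it < cfg.n_burnin
        # --- beta update (vectorized over chains x studies) ---
        prop = beta + np.exp(ls_beta) * rng.standard_normal((C, K))
        sp_p = _softplus(prop)
        sp_pd = _softplus(prop + delta)
        dlp = (
            (r1 + r2) * (prop - beta)
            - n1 * (sp_p - sp_b)
            - n2 * (sp_pd - sp_bd)
            - ((prop - hp.mu_beta) ** 2 - (beta - hp.mu_beta) ** 2)
            / (2.0 * hp.sigma_beta**2)
        )
        acc = np.log(rng.random((C, K))) < dlp
        beta = np.where(acc, prop, beta)
        sp_b = np.where(acc, sp_p, sp_b)
        sp_bd = np.where(acc, sp_pd, sp_bd)
        if adapting:
            batch_b += acc
        else:
            acc_b += acc

        # --- delta update ---
        prop = delta + np.exp(ls_delta) * rng.standard_normal((C, K))
        sp_pd = _softplus(beta + prop)
        dlp = (
            r2 * (prop - delta)
            - n2 * (sp_pd - sp_bd)
            - qv * ((prop - mu[:, None]) ** 2 - (delta - mu[:, None]) ** 2)
            / (2.0 * s2[:, None])
        )
        acc = np.log(rng.random((C, K))) < dlp
        delta = np.where(acc, prop, delta)
        sp_bd = np.where(acc, sp_pd, sp_bd)
        if adapting:
            batch_d += acc
        else:
            acc_d += acc

        # --- mu Gibbs ---
        tau = prec_mu + qsum / s2
        m = (hp.mu_mu * prec_mu + (qv * delta).sum(axis=1) / s2) / tau
        mu = m + rng.standard_normal(C) / np.sqrt(tau)

        # --- sigma2_theta Gibbs ---
        rate = hp.lam + 0.5 * (qv * (delta - mu[:, None]) ** 2).sum(axis=1)
        s2 = rate / rng.gamma(shape_s2, 1.0, size=C)

        # --- proposal adaptation, frozen after burn-in ---
        if adapting and (it + 1) % cfg.adapt_batch == 0:
            g = min(0.1, 1.0 / np.sqrt((it + 1) / cfg.adapt_batch))
            ls_beta += g * np.sign(batch_b / cfg.adapt_batch - cfg.target_accept)
            ls_delta += g * np.sign(batch_d / cfg.adapt_batch - cfg.target_accept)
            batch_b[:] = 0.0
            batch_d[:] = 0.0

        if not adapting and (it - cfg.n_burnin) % cfg.thinning == 0 and kept < n_kept:
            out_beta[:, kept] = beta
            out_delta[:, kept] = delta
            out_mu[:, kept] = mu
            out_s2[:, kept] = s2
            kept += 1

    rhat_mu = split_rhat(out_mu)
    rhat_s2 = split_rhat(np.log(out_s2))
    ess = _ess(out_mu)
    converged = bool(
        (not np.isfinite(rhat_mu) or rhat_mu <= rhat_threshold)
        and (not np.isfinite(rhat_s2) or rhat_s2 <= rhat_threshold)
    )
    return PosteriorSample(
        beta=out_beta,
        delta=out_delta,
        mu=out_mu,
        sigma2_theta=out_s2,
        q=qv,
        accept_beta=(acc_b / cfg.n_iterations).mean(axis=0),
        accept_delta=(acc_d / cfg.n_iterations).mean(axis=0),
        rhat_mu=rhat_mu,
        rhat_sigma2=rhat_s2,
        ess_mu=ess,
        converged=converged,
    )


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Each chain is split in half, so the statistic is defined even for a
    single chain.  Values near 1 indicate the half-chains agree in mean
    and variance.
    """
    C, N = draws.shape
    h = N // 2
    if h < 2:
        return np.nan
    halves = np.concatenate([draws[:, :h], draws[:, h : 2 * h]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    b = h * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return np.nan
    var_hat = (h - 1) / h * w + b / h
    return float(np.sqrt(var_hat / w))


def _ess(draws: np.ndarray) -> float:
    """Bulk effective sample size via arviz."""
    import arviz as az

    try:
        return float(az.ess(np.ascontiguousarray(draws)))
    except Exception:
        return float("nan")


def summarize(
    sample: PosteriorSample,
    t: float = 0.0,
    levels: Sequence[float] = (2.5, 5.0, 97.5),
) -> EffectSummary:
    """Posterior summaries of mu and the study effects delta_i.

    Percentiles are linear interpolation between order statistics of
    the pooled draws; the exceedance probability P(mu > t) is the
    fraction of pooled draws above the threshold.
    """
    mu = sample.pooled("mu")
    if mu.size == 0:
        raise DataValidationError("empty posterior sample")
    delta = sample.pooled("delta")
    pcts = {float(lv): float(np.percentile(mu, lv)) for lv in levels}
    return EffectSummary(
        mean_mu=float(mu.mean()),
        sd_mu=float(mu.std(ddof=1)),
        percentiles=pcts,
        exceedance=float(np.mean(mu > t)),
        threshold=float(t),
        delta_mean=delta.mean(axis=0),
        delta_lower=np.percentile(delta, 2.5, axis=0),
        delta_upper=np.percentile(delta, 97.5, axis=0),
    )
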