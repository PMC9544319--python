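"""Shared test helpers: independent density oracle and random states."""

import numpy as np
from scipy import stats
from scipy.special import expit

from robustmeta import ModelState


def naive_log_posterior(state, data, q, hp):
    """Independent term-by-term oracle using scipy densities only."""
    total = 0.0
    s2 = state.sigma2_theta
    if s2 <= 0:
        return -np.inf
    for i, s in enumerate(data.studies):
        p1 = expit(state.beta[i])
        p2 = expit(state.beta[i] + state.delta[i])
        total += stats.binom.logpmf(s.r_control, s.n_control, p1)
        total += stats.binom.logpmf(s.r_treatment, s.n_treatment, p2)
        total += stats.norm.logpdf(state.delta[i], state.mu, np.sqrt(s2 / q[i]))
        total += stats.norm.logpdf(state.beta[i], hp.mu_beta, hp.sigma_beta)
    total += stats.norm.logpdf(state.mu, hp.mu_mu, hp.sigma_mu)
    total += stats.invgamma.logpdf(s2, hp.alpha, scale=hp.lam)
    return total


def random_state(rng, K):
    return ModelState(
        beta=rng.normal(-2, 1, K),
        delta=rng.normal(1, 1, K),
        mu=rng.normal(1, 1),
        sigma2_theta=float(rng.gamma(2, 0.2)),
    )
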