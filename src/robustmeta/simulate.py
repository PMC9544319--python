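"""Forward simulator of the bias-adjusted model.

Generates study tables with known latent parameters by running the
model generatively: draw delta_i ~ Normal(mu, sigma2_theta / q_i), then
binomial responder counts at inverse-logit success probabilities.  Used
for parameter-recovery and calibration testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import DataValidationError
from .studies import StudyOutcome, StudyTable


@dataclass(frozen=True)
class SimScenario:
    """Ground-truth configuration for one simulated meta-analysis.

    ``beta`` may be given explicitly; otherwise each control log-odds
    is drawn from the Normal(0, 10^2) prior truncated to [-4, 4]
    (untruncated draws routinely produce all-or-nothing arms, which are
    unrealistic and break empirical display statistics, though not the
    model fit itself).
    """

    K: int
    n_control: Sequence[int] | int = 100
    n_treatment: Sequence[int] | int = 100
    mu: float = 0.0
    sigma2_theta: float = 0.1
    q: Sequence[float] | float = 1.0
    beta: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise DataValidationError("K must be >= 1")
        if self.sigma2_theta <= 0:
            raise DataValidationError("sigma2_theta must be > 0")
        qv = np.broadcast_to(np.asarray(self.q, dtype=float), (self.K,))
        if np.any(qv <= 0) or np.any(qv > 1):
            raise DataValidationError("all q_i must lie in (0, 1]")


def simulate(scenario: SimScenario) -> tuple[StudyTable, dict]:
    """Generate a StudyTable plus the latent truth record.

    Returns ``(table, truth)`` where ``truth`` holds mu, sigma2_theta,
    q, beta and delta used to generate the counts.  Fully reproducible
    under ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    K = scenario.K
    n1 = np.broadcast_to(np.asarray(scenario.n_control, dtype=int), (K,))
    n2 = np.broadcast_to(np.asarray(scenario.n_treatment, dtype=int), (K,))
    qv = np.broadcast_to(np.asarray(scenario.q, dtype=float), (K,))
    if scenario.beta is not None:
        beta = np.asarray(scenario.beta, dtype=float)
        if beta.shape != (K,):
            raise DataValidationError(f"beta must have length K={K}")
    else:
        beta = np.empty(K)
        for i in range(K):  # rejection sampling from the truncated prior
            while True:
                b = rng.normal(0.0, 10.0)
                if -4.0 <= b <= 4.0:
                    beta[i] = b
                    break
    delta = rng.normal(scenario.mu, np.sqrt(scenario.sigma2_theta / qv))
    p1 = expit(beta)
    p2 = expit(beta + delta)
    r1 = rng.binomial(n1, p1)
    r2 = rng.binomial(n2, p2)
    studies = tuple(
        StudyOutcome(
            study_id=f"SIM{i + 1:03d}",
            r_control=int(r1[i]),
            n_control=int(n1[i]),
            r_treatment=int(r2[i]),
            n_treatment=int(n2[i]),
        )
        for i in range(K)
    )
    truth = {
        "mu": float(scenario.mu),
        "sigma2_theta": float(scenario.sigma2_theta),
        "q": qv.tolist(),
        "beta": beta.tolist(),
        "delta": delta.tolist(),
        "seed": int(scenario.seed),
    }
    return StudyTable(studies=studies), truth


def write_truth(truth: dict, path: str | Path) -> None:
    """Sidecar JSON with the latent truth, for test harness consumption."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
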