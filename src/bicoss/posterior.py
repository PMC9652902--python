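"""Bayesian scoring of SNP models.

Bayes factors are approximated from BIC differences,
BF_ib ≈ exp{-0.5 (BIC_i - BIC_b)}, which corresponds to a unit-information
prior on the model parameters and needs no explicit prior densities.  The
model space carries an independent-Bernoulli prior: each of the s eligible
SNPs enters with probability 1 - pi0, so P(M_i) = pi0^(s-p_i) (1-pi0)^p_i
for a model with p_i SNPs.  pi0, the proportion of true null SNPs, is
estimated from single-marker p-values by Storey's smoother; when that
estimate is conservative (>= 1) the fallback pi0 = 1 - 100/L is used, i.e.
a prior expectation of 100 causal SNPs genome-wide.

All Bayes-factor arithmetic is done in log space with |log BF| clamped at
700 to stay inside double range.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import logsumexp

__all__ = [
    "ModelPrior",
    "SNPModel",
    "PriorSource",
    "bayes_factor_approx",
    "log_bayes_factor",
    "prior_model_prob",
    "estimate_pi0",
    "snp_posterior",
    "posterior_over_models",
]

LOG_BF_CLAMP = 700.0


class PriorSource(str, Enum):
    estimated = "estimated"
    fallback = "fallback"


@dataclass(frozen=True)
class ModelPrior:
    """Bernoulli model-space prior with null proportion pi0 over s SNPs."""

    pi0: float
    s: int
    source: PriorSource = PriorSource.estimated

    def __post_init__(self):
        if not (0.0 < self.pi0 < 1.0):
            raise ValueError(f"pi0 must lie in (0, 1), got {self.pi0}")

    def with_s(self, s: int) -> "ModelPrior":
        return ModelPrior(pi0=self.pi0, s=int(s), source=self.source)

    @property
    def log_odds(self) -> float:
        """log((1 - pi0) / pi0), the per-SNP prior inclusion log-odds."""
        return float(np.log1p(-self.pi0) - np.log(self.pi0))


@dataclass
class SNPModel:
    """A candidate model: a SNP index set with its evidence summaries."""

    snps: tuple[int, ...]
    bic: float
    bf_vs_base: float
    log_prior: float
    posterior: float

    @property
    def p(self) -> int:
        return len(self.snps)


def log_bayes_factor(bic_i: float, bic_b: float) -> float:
    """log BF of model i vs the base model from their BICs, clamped."""
    if not (np.isfinite(bic_i) and np.isfinite(bic_b)):
        raise ValueError("BIC inputs must be finite")
    return float(np.clip(-0.5 * (bic_i - bic_b), -LOG_BF_CLAMP, LOG_BF_CLAMP))


def bayes_factor_approx(bic_i: float, bic_b: float) -> float:
    """BIC approximation to the Bayes factor, exp{-0.5 (BIC_i - BIC_b)}."""
    return float(np.exp(log_bayes_factor(bic_i, bic_b)))


def prior_model_prob(prior: ModelPrior, p_i: int) -> float:
    """Log prior probability of a model containing p_i of the s SNPs."""
    if p_i < 0 or p_i > prior.s:
        raise ValueError(f"model size {p_i} outside [0, {prior.s}]")
    return float(
        (prior.s - p_i) * np.log(prior.pi0) + p_i * np.log1p(-prior.pi0)
    )


_LAMBDA_GRID = np.arange(0.05, 0.951, 0.05)


def estimate_pi0(pvalues: np.ndarray, L: int) -> ModelPrior:
    """Storey-type estimate of the proportion of true null SNPs.

    pi0_hat(lambda) = #{p > lambda} / (L_eff (1 - lambda)) is computed on
    lambda = 0.05, 0.10, ..., 0.95, smoothed by a natural cubic spline and
    read off at lambda = 0.95.  A conservative estimate >= 1 triggers the
    fallback pi0 = 1 - 100/L.

    NaN entries (e.g. base-model SNPs skipped by the screen) are ignored.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("cannot estimate pi0 from an empty p-value vector")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0_lam = np.array(
        [(p > lam).sum() / (m * (1.0 - lam)) for lam in _LAMBDA_GRID]
    )
    spline = CubicSpline(_LAMBDA_GRID, pi0_lam, bc_type="natural")
    pi0 = float(spline(_LAMBDA_GRID[-1]))
    if pi0 >= 1.0 or pi0 <= 0.0:
        # 1 - 100/L presumes genome-scale L; clamp so tiny panels stay valid
        fb = float(np.clip(1.0 - 100.0 / L, 0.5, 1.0 - 1e-12))
        return ModelPrior(pi0=fb, s=L, source=PriorSource.fallback)
    return ModelPrior(pi0=pi0, s=L, source=PriorSource.estimated)


def snp_posterior(bf, prior: ModelPrior, *, log: bool = False):
    """Posterior inclusion probability of one SNP vs the base model.

    The two-model special case: p = (1-pi0) BF / (pi0 + (1-pi0) BF).
    Accepts scalars or arrays; with ``log=True`` the first argument is
    log BF (numerically safer for extreme evidence).
    """
    bf = np.asarray(bf, dtype=float)
    if log:
        lbf = bf
    else:
        if np.any(bf < 0):
            raise ValueError("Bayes factors must be non-negative")
        with np.errstate(divide="ignore"):
            lbf = np.log(bf)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-(lbf + prior.log_odds)))
    out = np.asarray(np.where(np.isneginf(lbf), 0.0, out))
    return float(out) if out.ndim == 0 else out


def posterior_over_models(models: list[SNPModel], prior: ModelPrior) -> list[SNPModel]:
    """Normalize posterior probabilities over a scored model collection.

    Posteriors are proportional to exp{log_prior + log BF}; normalization
    uses log-sum-exp.  The models are updated in place and returned.
    """
    if not models:
        raise ValueError("cannot normalize an empty model collection")
    logw = np.array(
        [m.log_prior + np.log(max(m.bf_vs_base, 0.0)) if m.bf_vs_base > 0
         else -np.inf for m in models]
    )
    logz = logsumexp(logw)
    post = np.exp(logw - logz)
    for m, p in zip(models, post):
        m.posterior = float(p)
    return models
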