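"""Residual single-SNP screen with Bayesian FDR candidate selection.

Each SNP not already in the base model is regressed, without intercept,
against the base-model residuals Yhat under the singular error covariance
sigma^2 Sigma(tau_hat).  Working in the retained eigenbasis of Sigma with
unit-variance scaling ("whitening") turns every per-SNP fit into ordinary
least squares on rank(Sigma) pseudo-observations; the BIC of the one-SNP
model vs the empty model yields the Bayes factor and, with the Bernoulli
model prior, the posterior inclusion probability p_l.

Candidates are chosen by Bayesian FDR control: SNPs are ranked by
decreasing p_l and the largest prefix whose posterior expected FDR,
FDRhat_d = sum_{l<=d}(1 - p_(l)) / d, stays below the nominal level q0 is
flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lmm import SigmaFactor
from .posterior import ModelPrior, snp_posterior

__all__ = ["ScreeningResult", "screen_snps", "bayesian_fdr_select"]

logger = logging.getLogger(__name__)


@dataclass
class ScreeningResult:
    """Per-SNP screening evidence and the FDR-selected candidate set."""

    p_post: np.ndarray  # (L,) posterior inclusion probabilities, NaN for base SNPs
    pvals: np.ndarray  # (L,) whitened Wald p-values (feed the pi0 estimator)
    log_bf: np.ndarray  # (L,) log Bayes factors of one-SNP vs empty model
    betas: np.ndarray  # (L,) whitened GLS slope estimates
    ses: np.ndarray  # (L,) their standard errors
    prior_used: ModelPrior | None = None
    candidates: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    fdr_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    q0: float = 0.05


def screen_snps(
    Yhat: np.ndarray,
    sigma: SigmaFactor,
    G: np.ndarray,
    base_snps=(),
    prior: ModelPrior | None = None,
) -> ScreeningResult:
    """Score every SNP outside the base model against the residuals.

    Returns a :class:`ScreeningResult` without candidate selection; apply
    :func:`bayesian_fdr_select` (or pass the result to the driver) for the
    candidate set.  If ``prior`` is None only log BFs, betas and p-values
    are filled and ``p_post`` is left NaN.
    """
    G = np.asarray(G, dtype=float)
    L = G.shape[1]
    base = set(int(s) for s in base_snps)
    ystar = sigma.whiten(np.asarray(Yhat, dtype=float))
    m = sigma.rank
    Gstar = sigma.whiten(G)

    sxx = np.einsum("ij,ij->j", Gstar, Gstar)
    sxy = Gstar.T @ ystar
    syy = float(ystar @ ystar)

    log_bf = np.full(L, np.nan)
    betas = np.full(L, np.nan)
    ses = np.full(L, np.nan)
    pvals = np.full(L, np.nan)

    degenerate = sxx <= 1e-12 * max(float(sxx.max(initial=0.0)), 1.0)
    n_degen = int(sum(degenerate[l] for l in range(L) if l not in base))
    if n_degen:
        logger.warning(
            "%d SNP(s) have zero variance after projection; assigned p_l = 0",
            n_degen,
        )
    ok = ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        rss1 = np.maximum(syy - np.where(ok, sxy**2 / np.where(ok, sxx, 1.0), 0.0), 1e-300)
    # BIC difference of one-SNP vs empty model at sample size m (retained rank);
    # sigma^2 terms share a parameter so the penalty difference is one log(m)
    dbic = m * (np.log(rss1) - np.log(syy)) + np.log(m)
    lbf = np.clip(-0.5 * dbic, -700.0, 700.0)
    se = np.sqrt((rss1 / (m - 1)) / np.where(ok, sxx, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pv = 2.0 * stats.t.sf(np.abs(tstat), df=m - 1)

    keep = np.array([l not in base for l in range(L)])
    fill = keep & ok
    log_bf[fill] = lbf[fill]
    betas[fill] = beta[fill]
    ses[fill] = se[fill]
    pvals[fill] = pv[fill]
    dead = keep & ~ok
    log_bf[dead] = -np.inf
    betas[dead] = 0.0
    pvals[dead] = 1.0

    p_post = np.full(L, np.nan)
    if prior is not None:
        p_post[keep] = snp_posterior(log_bf[keep], prior, log=True)
    res = ScreeningResult(
        p_post=p_post, pvals=pvals, log_bf=log_bf, betas=betas, ses=ses,
        prior_used=prior,
    )
    return res


def bayesian_fdr_select(p_post: np.ndarray, q0: float = 0.05):
    """Flag the largest prefix of posterior-ranked SNPs with FDRhat < q0.

    SNPs are sorted by decreasing posterior probability (ties broken by
    ascending index); the posterior expected FDR of taking the first d is
    the running mean of (1 - p).  NaN entries are ignored.

    Returns ``(candidates, fdr_curve)`` with candidates in ascending index
    order and ``fdr_curve[d-1]`` the FDR estimate for the d-SNP prefix.
    """
    p = np.asarray(p_post, dtype=float).ravel()
    if not (0.0 < q0 < 1.0):
        raise ValueError("q0 must lie in (0, 1)")
    valid = np.flatnonzero(~np.isnan(p))
    if valid.size == 0:
        return np.empty(0, dtype=int), np.empty(0)
    order = valid[np.lexsort((valid, -p[valid]))]
    fdr_curve = np.cumsum(1.0 - p[order]) / np.arange(1, order.size + 1)
    below = fdr_curve < q0
    d = int(np.max(np.flatnonzero(below)) + 1) if below.any() else 0
    candidates = np.sort(order[:d])
    return candidates, fdr_curve
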