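"""Single-marker-analysis baselines with Bonferroni correction.

Three variants are provided:

* ``sma_exact`` — for each SNP the mixed model is refit with the kinship
  dependence parameter tau re-maximized per SNP via the spectral profile
  likelihood (EMMA-style).
* ``sma_approx`` — tau is estimated once from the no-SNP null model and
  held fixed for every per-SNP GLS fit (EMMAX-style).
* ``sma_ols`` — simple linear regression per SNP with the classic t test,
  ignoring kinship entirely.

All variants report two-sided Wald p-values for the SNP coefficient and a
Bonferroni-significant set at family-wise level 0.05 (p < 0.05 / L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GWASData
from .lmm import SpectralBasis, eigen_rotate, fit_lmm

__all__ = ["SMAResult", "sma_exact", "sma_approx", "sma_ols"]

logger = logging.getLogger(__name__)

ALPHA_FAMILY = 0.05


@dataclass
class SMAResult:
    pvals: np.ndarray
    betas: np.ndarray
    ses: np.ndarray
    tau_hats: np.ndarray  # per-SNP for exact; broadcast scalar otherwise
    significant: np.ndarray  # indices with p < 0.05 / L
    method: str  # exact | approx | ols

    @property
    def L(self) -> int:
        return self.pvals.shape[0]


def _finish(pvals, betas, ses, tau_hats, method) -> SMAResult:
    pvals = np.asarray(pvals, dtype=float)
    sig = np.flatnonzero(pvals < ALPHA_FAMILY / pvals.size)
    return SMAResult(
        pvals=pvals, betas=np.asarray(betas, dtype=float),
        ses=np.asarray(ses, dtype=float), tau_hats=np.asarray(tau_hats, dtype=float),
        significant=sig, method=method,
    )


def _per_snp_stats(Xc: np.ndarray, Gt: np.ndarray, yt: np.ndarray, w: np.ndarray):
    """Vectorized per-SNP weighted regression via covariate sweep-out.

    For the design [Xc | g_l] with weights w, partials out Xc from y and
    every genotype column, then runs the closed-form one-variable fit.
    Returns (beta, sxx, rss, syy_null) per SNP; sxx = 0 marks degenerate
    columns.
    """
    Xw = Xc * w[:, None]
    A = Xc.T @ Xw
    By = Xw.T @ yt
    cy = np.linalg.solve(A, By)
    Bg = Xw.T @ Gt
    Cg = np.linalg.solve(A, Bg)
    syy = float(yt @ (w * yt) - By @ cy)
    sxx = np.einsum("ij,ij->j", Gt, Gt * w[:, None]) - np.einsum("ij,ij->j", Bg, Cg)
    sxy = Gt.T @ (w * yt) - Bg.T @ cy
    sxx = np.maximum(sxx, 0.0)
    ok = sxx > 1e-12 * max(float(sxx.max(initial=0.0)), 1.0)
    beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
    rss = np.maximum(syy - np.where(ok, sxy**2 / np.where(ok, sxx, 1.0), 0.0), 1e-300)
    return beta, np.where(ok, sxx, 0.0), rss, syy


def _wald(beta, sxx, rss, df):
    ok = sxx > 0
    se = np.sqrt(np.where(ok, (rss / df) / np.where(ok, sxx, 1.0), np.inf))
    t = np.where(ok, beta / se, 0.0)
    p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), df=df), 1.0)
    return se, p


def sma_exact(
    data: GWASData, basis: SpectralBasis | None = None, n_grid: int = 50, n_refine: int = 25
) -> SMAResult:
    """EMMA-style SMA: tau re-maximized for every SNP.

    The per-SNP profile likelihood is evaluated on a log-spaced tau grid
    (vectorized over all SNPs at once) and refined on a finer local grid
    around each SNP's best coarse point.
    """
    if basis is None:
        basis = eigen_rotate(data.Z, data.K)
    n, L = data.n, data.L
    lam = basis.lambdas
    Xc = basis.rotate(data.X_cov)
    Gt = basis.rotate(data.G)
    yt = basis.rotate(data.Y)
    c = data.c
    taus = np.logspace(-6, 6, n_grid)

    def lls_at(tau_vec, cols):
        """Profile log-likelihood matrix, one row per tau, for SNP cols."""
        out = np.empty((len(tau_vec), cols.shape[1]))
        for i, tau in enumerate(tau_vec):
            a = 1.0 + tau * lam
            w = 1.0 / a
            _, _, rss, _ = _per_snp_stats(Xc, cols, yt, w)
            out[i] = -0.5 * (n * np.log(2 * np.pi * rss / n) + np.log(a).sum() + n)
        return out

    lls = lls_at(taus, Gt)
    best_idx = np.argmax(lls, axis=0)
    tau_hat = taus[best_idx].astype(float)
    # local refinement, grouped by coarse optimum to stay vectorized
    for i in np.unique(best_idx):
        lo = taus[max(i - 1, 0)]
        hi = taus[min(i + 1, n_grid - 1)]
        if hi <= lo:
            continue
        grid = np.logspace(np.log10(lo), np.log10(hi), n_refine)
        members = np.flatnonzero(best_idx == i)
        sub = lls_at(grid, Gt[:, members])
        pick = np.argmax(sub, axis=0)
        improve = sub[pick, np.arange(members.size)] > lls[i, members]
        tau_hat[members[improve]] = grid[pick[improve]]

    betas = np.empty(L)
    ses = np.empty(L)
    pvals = np.empty(L)
    for tau in np.unique(tau_hat):
        members = np.flatnonzero(tau_hat == tau)
        w = 1.0 / (1.0 + tau * lam)
        beta, sxx, rss, _ = _per_snp_stats(Xc, Gt[:, members], yt, w)
        se, p = _wald(beta, sxx, rss, df=n - c - 1)
        betas[members], ses[members], pvals[members] = beta, se, p
    if np.any(ses == np.inf):
        logger.warning("%d monomorphic SNP(s) set to p = 1", int((ses == np.inf).sum()))
    return _finish(pvals, betas, ses, tau_hat, "exact")


def sma_approx(data: GWASData, basis: SpectralBasis | None = None) -> SMAResult:
    """EMMAX-style SMA: variance parameters fixed from the no-SNP model."""
    if basis is None:
        basis = eigen_rotate(data.Z, data.K)
    null_fit = fit_lmm(data, (), basis=basis)
    tau = null_fit.tau_hat
    w = 1.0 / (1.0 + tau * basis.lambdas)
    Xc = basis.rotate(data.X_cov)
    Gt = basis.rotate(data.G)
    yt = basis.rotate(data.Y)
    beta, sxx, rss, _ = _per_snp_stats(Xc, Gt, yt, w)
    se, p = _wald(beta, sxx, rss, df=data.n - data.c - 1)
    return _finish(p, beta, se, np.full(data.L, tau), "approx")


def sma_ols(data: GWASData) -> SMAResult:
    """Per-SNP simple linear regression with the classic t statistic."""
    n, L = data.n, data.L
    y = data.Y - data.Y.mean()
    G = data.G - data.G.mean(axis=0)
    sxx = np.einsum("ij,ij->j", G, G)
    ok = sxx > 1e-12 * max(float(sxx.max(initial=0.0)), 1.0)
    sxy = G.T @ y
    beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
    rss = np.maximum(
        float(y @ y) - np.where(ok, sxy**2 / np.where(ok, sxx, 1.0), 0.0), 1e-300
    )
    se, p = _wald(beta, np.where(ok, sxx, 0.0), rss, df=n - 2)
    return _finish(p, beta, se, np.zeros(L), "ols")
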