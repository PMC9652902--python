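"""Kinship linear mixed model fitted by maximum likelihood.

The model is Y = X beta + Z u + eps with u ~ N(0, sigma^2 tau K) and
eps ~ N(0, sigma^2 I), so marginally Y ~ N(X beta, sigma^2 (I + tau ZKZ')).
A single spectral decomposition ZKZ' = U diag(lambda) U' turns every fit,
for any tau, into a weighted least squares problem in the rotated
coordinates U'Y — the standard EMMA device.  The kinship dependence
parameter tau is profiled out on a log-scale grid followed by bounded
scalar refinement; beta and sigma^2 then have closed forms.

BIC uses the ML (not REML) likelihood so that BIC differences approximate
-2 log Bayes factors under a unit-information prior; the parameter count
``d`` includes every design column plus sigma^2 and tau.  REML is available
as an off-by-default option for variance-component diagnostics only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .data import GWASData

__all__ = ["SpectralBasis", "LMMFit", "SigmaFactor", "eigen_rotate", "fit_lmm", "residualize"]

TAU_LO = 1e-6
TAU_HI = 1e6
_TAU_GRID = np.logspace(math.log10(TAU_LO), math.log10(TAU_HI), 100)
LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SpectralBasis:
    """Eigendecomposition of ZKZ': ZKZ' = U diag(lambdas) U'."""

    lambdas: np.ndarray  # (n,), >= 0
    U: np.ndarray  # (n, n) orthonormal

    @property
    def n(self) -> int:
        return self.lambdas.shape[0]

    def rotate(self, M: np.ndarray) -> np.ndarray:
        """Coordinates of M in the eigenbasis, U' M."""
        return self.U.T @ M


@dataclass
class LMMFit:
    """One maximum-likelihood fit of the mixed model for a fixed SNP set."""

    model_snps: tuple[int, ...]
    beta_hat: np.ndarray  # covariates first, then SNPs in model_snps order
    sigma2_hat: float
    tau_hat: float
    loglik: float
    d: int
    bic: float
    n: int
    tau_profiled: bool  # False when tau was supplied (P3D)


@dataclass(frozen=True)
class SigmaFactor:
    """Reduced-rank eigenfactorization of the screening covariance Sigma(tau).

    Sigma = A - X (X' A^{-1} X)^{-1} X' with A = I + tau ZKZ' is the
    covariance of the GLS residuals Y - X beta_hat (up to sigma^2).  It is
    singular with rank n - rank(X); the retained eigenpairs (eigenvalues
    above 1e-10 of the largest) define the whitening used by the screen.
    """

    V: np.ndarray  # (n, r) retained eigenvectors
    d: np.ndarray  # (r,) retained eigenvalues, > 0
    tau: float
    rank: int

    def whiten(self, M: np.ndarray) -> np.ndarray:
        """Project onto the retained eigenbasis and scale to unit variance."""
        return (self.V.T @ M) / np.sqrt(self.d)[:, None] if M.ndim == 2 else (
            self.V.T @ M
        ) / np.sqrt(self.d)

    def dense(self) -> np.ndarray:
        return (self.V * self.d) @ self.V.T


def eigen_rotate(Z: np.ndarray, K: np.ndarray) -> SpectralBasis:
    """Spectral decomposition of the covariance kernel ZKZ'.

    Eigenvalues are clipped at zero so that 1 + tau*lambda is a valid
    variance weight for every tau >= 0.
    """
    K = np.asarray(K, dtype=float)
    if np.isnan(K).any():
        raise ValueError("kinship matrix contains NaN")
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be square and symmetric")
    Z = np.asarray(Z, dtype=float)
    Kt = Z @ K @ Z.T
    Kt = 0.5 * (Kt + Kt.T)
    lam, U = np.linalg.eigh(Kt)
    return SpectralBasis(lambdas=np.clip(lam, 0.0, None), U=U)


def _design(data: GWASData, model_snps) -> tuple[np.ndarray, tuple[int, ...]]:
    snps = tuple(int(s) for s in model_snps)
    M = np.hstack([data.X_cov, data.G[:, list(snps)]]) if snps else data.X_cov
    return M, snps


def _check_rank(M: np.ndarray, data: GWASData, snps) -> None:
    r = np.linalg.matrix_rank(M)
    if r < M.shape[1]:
        # name the offending columns for the caller
        labels = [f"cov{j}" for j in range(data.c)] + [
            data.snp_label(s) for s in snps
        ]
        q, rmat = np.linalg.qr(M)
        diag = np.abs(np.diag(rmat))
        bad = [labels[j] for j in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(
            f"rank-deficient design (rank {r} < {M.shape[1]}); "
            f"collinear columns involve {bad}"
        )


def _wls(Mt: np.ndarray, yt: np.ndarray, w: np.ndarray):
    """Weighted LS in rotated coordinates; returns (beta, weighted RSS)."""
    Mw = Mt * w[:, None]
    A = Mt.T @ Mw
    b = Mw.T @ yt
    beta = np.linalg.solve(A, b)
    resid = yt - Mt @ beta
    rss = float(np.sum(w * resid**2))
    return beta, rss


def _profile_ll(tau: float, Mt, yt, lam, n: int, reml: bool = False) -> float:
    a = 1.0 + tau * lam
    w = 1.0 / a
    beta, rss = _wls(Mt, yt, w)
    if reml:
        p = Mt.shape[1]
        sigma2 = rss / (n - p)
        A = (Mt * w[:, None]).T @ Mt
        sign, logdet = np.linalg.slogdet(A)
        ll = -0.5 * (
            (n - p) * (LOG2PI + math.log(sigma2))
            + np.log(a).sum()
            + logdet
            + (n - p)
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * (LOG2PI + math.log(sigma2)) + np.log(a).sum() + n)
    return ll


def fit_lmm(
    data: GWASData,
    model_snps=(),
    tau_fixed: float | None = None,
    basis: SpectralBasis | None = None,
    reml: bool = False,
) -> LMMFit:
    """ML fit of the mixed model with the given SNPs as fixed effects.

    Parameters
    ----------
    model_snps : iterable of SNP column indices included as fixed effects.
    tau_fixed : if given, tau is held at this value (P3D-style) instead of
        being profiled.
    basis : precomputed :func:`eigen_rotate` result, reused across fits.
    reml : profile the REML criterion instead of ML (BIC still reported
        from the ML-style plug-in likelihood at the REML tau).
    """
    M, snps = _design(data, model_snps)
    _check_rank(M, data, snps)
    if basis is None:
        basis = eigen_rotate(data.Z, data.K)
    n = data.n
    lam = basis.lambdas
    Mt = basis.rotate(M)
    yt = basis.rotate(data.Y)

    if tau_fixed is not None:
        tau_hat = float(tau_fixed)
        tau_profiled = False
    else:
        lls = np.array([_profile_ll(t, Mt, yt, lam, n, reml) for t in _TAU_GRID])
        # ties (within optimizer tolerance) break toward smaller tau: with a
        # flat profile (e.g. K = I) the parsimonious tau is reported
        tol = 1e-9 * max(1.0, abs(lls.max()))
        i = int(np.flatnonzero(lls >= lls.max() - tol)[0])
        lo = _TAU_GRID[max(i - 1, 0)]
        hi = _TAU_GRID[min(i + 1, len(_TAU_GRID) - 1)]
        tau_hat = _TAU_GRID[i]
        if hi > lo:
            res = minimize_scalar(
                lambda lt: -_profile_ll(math.exp(lt), Mt, yt, lam, n, reml),
                bounds=(math.log(lo), math.log(hi)),
                method="bounded",
                options={"xatol": 1e-8},
            )
            if -res.fun > lls[i] + tol:
                tau_hat = math.exp(res.x)
        tau_profiled = True

    a = 1.0 + tau_hat * lam
    w = 1.0 / a
    beta, rss = _wls(Mt, yt, w)
    sigma2 = rss / n
    loglik = -0.5 * (n * (LOG2PI + math.log(sigma2)) + np.log(a).sum() + n)
    d = M.shape[1] + 2  # design columns + sigma^2 + tau
    bic = -2.0 * loglik + d * math.log(n)
    return LMMFit(
        model_snps=snps,
        beta_hat=beta,
        sigma2_hat=sigma2,
        tau_hat=float(tau_hat),
        loglik=float(loglik),
        d=d,
        bic=float(bic),
        n=n,
        tau_profiled=tau_profiled,
    )


EIG_RTOL = 1e-10  # relative eigenvalue cutoff for the singular covariance


def residualize(
    data: GWASData, fit: LMMFit, basis: SpectralBasis | None = None
) -> tuple[np.ndarray, SigmaFactor]:
    """Fixed-effect residuals and the factored covariance of the screen.

    Returns ``(Yhat, Sigma_factor)`` where ``Yhat = Y - X beta_hat`` (the
    random effect is *not* subtracted) and ``Sigma_factor`` is the rank
    n - rank(X) eigenfactorization of

        Sigma(tau) = A - X (X' A^{-1} X)^{-1} X',   A = I + tau ZKZ',

    the covariance (up to sigma^2) of the GLS residual vector.  Sigma
    annihilates A^{-1} X, which is the direction the residuals cannot vary
    in; at tau = 0 and X = intercept it is the usual centering matrix.
    """
    if basis is None:
        basis = eigen_rotate(data.Z, data.K)
    M, snps = _design(data, fit.model_snps)
    Yhat = data.Y - M @ fit.beta_hat
    a = 1.0 + fit.tau_hat * basis.lambdas
    Mt = basis.rotate(M)
    # Sigma in rotated coordinates: diag(a) - Mt (Mt' diag(1/a) Mt)^{-1} Mt'
    A_inv_M = Mt / a[:, None]
    gram = Mt.T @ A_inv_M
    S = np.diag(a) - Mt @ np.linalg.solve(gram, Mt.T)
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    cutoff = EIG_RTOL * evals.max()
    keep = evals > cutoff
    rank = int(keep.sum())
    V = basis.U @ evecs[:, keep]
    return Yhat, SigmaFactor(V=V, d=evals[keep], tau=fit.tau_hat, rank=rank)
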