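"""Container and validation for one GWAS analysis.

A :class:`GWASData` bundles the phenotype vector, the dosage-coded genotype
matrix, fixed covariates (always led by an intercept column), the
strain-incidence matrix ``Z`` and the kinship matrix ``K`` of the linear
mixed model

    Y = X beta + Z u + eps,   u ~ N(0, sigma^2 tau K),   eps ~ N(0, sigma^2 I).

``Z`` maps each of the ``n`` phenotyped individuals to one of ``t`` inbred
strains; for typical panels of unreplicated accessions ``Z = I`` and
``t = n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GWASData", "find_aliases", "maf_filter"]


def _as_2d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class GWASData:
    """Aligned inputs for one analysis.

    Parameters
    ----------
    Y : (n,) phenotype vector.
    G : (n, L) genotype matrix, minor-allele dosages in {0, 1, 2}
        (fractional values are allowed after mean imputation).
    X_cov : (n, c) covariate matrix whose first column is the intercept;
        defaults to the intercept alone.
    Z : (n, t) 0/1 incidence matrix, one 1 per row; defaults to identity.
    K : (t, t) kinship (realized relationship) matrix, symmetric PSD.
    snp_ids : optional DataFrame with columns ``snp_id``, ``chrom``, ``pos``.
    """

    Y: np.ndarray
    G: np.ndarray
    X_cov: np.ndarray | None = None
    Z: np.ndarray | None = None
    K: np.ndarray | None = None
    snp_ids: pd.DataFrame | None = None
    sample_ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        n = self.Y.shape[0]
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("phenotype vector contains non-finite values")
        self.G = _as_2d(self.G, "G")
        if self.G.shape[0] != n:
            raise ValueError(
                f"G has {self.G.shape[0]} rows but phenotype has length {n}"
            )
        if self.X_cov is None:
            self.X_cov = np.ones((n, 1))
        else:
            self.X_cov = _as_2d(self.X_cov, "X_cov")
            if self.X_cov.shape[0] != n:
                raise ValueError("X_cov row count does not match phenotype length")
            if not np.allclose(self.X_cov[:, 0], 1.0):
                raise ValueError("first column of X_cov must be the intercept")
        if self.Z is None:
            self.Z = np.eye(n)
        else:
            self.Z = _as_2d(self.Z, "Z")
            if self.Z.shape[0] != n:
                raise ValueError("Z row count does not match phenotype length")
            ok = np.all(np.isin(self.Z, (0.0, 1.0))) and np.all(
                self.Z.sum(axis=1) == 1
            )
            if not ok:
                raise ValueError("each row of Z must contain exactly one 1")
        t = self.Z.shape[1]
        if self.K is None:
            self.K = np.eye(t)
        else:
            self.K = _as_2d(self.K, "K")
            if np.isnan(self.K).any():
                raise ValueError("kinship matrix contains NaN")
            if self.K.shape != (t, t):
                raise ValueError(f"K must be {t}x{t} to match Z")
            if not np.allclose(self.K, self.K.T, atol=1e-8):
                raise ValueError("kinship matrix must be symmetric")
            ev = np.linalg.eigvalsh(self.K)
            if ev.min() < -1e-8 * max(ev.max(), 1.0):
                raise ValueError("kinship matrix is not positive semi-definite")
        if self.snp_ids is not None and len(self.snp_ids) != self.G.shape[1]:
            raise ValueError("snp_ids length does not match number of SNP columns")
        # constant genotype columns break every downstream regression
        if self.G.shape[1] and np.any(self.G.std(axis=0) == 0):
            bad = np.flatnonzero(self.G.std(axis=0) == 0)[:5]
            raise ValueError(
                f"constant genotype column(s) {bad.tolist()}; apply a MAF filter first"
            )

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def L(self) -> int:
        return self.G.shape[1]

    @property
    def t(self) -> int:
        return self.Z.shape[1]

    @property
    def c(self) -> int:
        return self.X_cov.shape[1]

    def snp_label(self, idx: int) -> str:
        if self.snp_ids is not None:
            return str(self.snp_ids.iloc[idx]["snp_id"])
        return f"snp{idx}"


def maf_filter(G: np.ndarray, maf_min: float = 0.01):
    """Indices of SNP columns with minor allele frequency > ``maf_min``.

    Returns ``(kept_indices, removed_indices)``.  Dosages are assumed
    minor-allele coded but the frequency is folded defensively.
    """
    freq = np.asarray(G, dtype=float).mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.flatnonzero(maf > maf_min)
    drop = np.flatnonzero(maf <= maf_min)
    return keep, drop


def find_aliases(G: np.ndarray, indices) -> tuple[list[int], dict[int, list[int]]]:
    """Resolve perfectly correlated SNPs among ``indices``.

    SNP columns with |sample correlation| = 1 are indistinguishable in any
    regression design; of each such group the lowest index is kept and the
    rest are reported as its aliases.

    Returns ``(kept, aliases)`` where ``aliases`` maps each kept index to the
    (possibly empty) list of dropped indices it represents.
    """
    idx = sorted(int(i) for i in indices)
    if not idx:
        return [], {}
    cols = np.asarray(G, dtype=float)[:, idx]
    sd = cols.std(axis=0)
    std = (cols - cols.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    corr = std.T @ std / cols.shape[0]
    kept: list[int] = []
    aliases: dict[int, list[int]] = {}
    owner = {}  # position in idx -> kept snp index
    for j, snp in enumerate(idx):
        merged = False
        for i in range(j):
            if abs(corr[i, j]) >= 1.0 - 1e-12:
                aliases[owner[i]].append(snp)
                owner[j] = owner[i]
                merged = True
                break
        if not merged:
            kept.append(snp)
            aliases[snp] = []
            owner[j] = snp
    return kept, aliases
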