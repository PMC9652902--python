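"""Synthetic GWAS generator: LD-block genotypes, kinship, phenotypes.

Genotypes are biallelic minor-allele dosages drawn per LD block from a
latent Gaussian AR(1) process thresholded at Hardy-Weinberg quantiles for
a per-SNP minor allele frequency drawn from [maf_min, 0.5]; blocks are
mutually independent.  The default settings mirror a dense plant-panel
design: 328 inbred accessions, 10 blocks of 6000 SNPs (60,000 total), MAF
at least 0.01, and causal SNPs at the block centers.  The default
within-block adjacent correlation rho = 0.9 emulates the strong local LD
of selfing species; rho = 0 gives independent SNPs.

Phenotypes come from the mixed model

    Y = alpha 1 + G beta + Z u + eps,  u ~ N(0, sigma^2 tau K),
                                       eps ~ N(0, sigma^2 I),

with alpha = 1, tau = 0.1, sigma^2 = 0.2 by default; the ``null`` variant
drops the genetic effects (beta absent) and the ``linear`` variant drops
the random effect (no kinship structure).  The kinship matrix is the
VanRaden realized-relationship matrix computed from the simulated
genotypes themselves.

Effect-size patterns follow the ten-causal-SNP benchmark design: seven
coefficients fixed at 0.4 and three equal coefficients beta1 taking values
in {0.05, 0.1, 0.2, 0.4, 0.8, 1.6}, arranged
(beta1, .4, .4, .4, beta1, .4, .4, .4, beta1, .4).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimSettings",
    "SimTruth",
    "beta_pattern",
    "default_causal_positions",
    "simulate_genotypes",
    "build_kinship",
    "simulate_phenotype",
    "simulate_dataset",
    "write_plink",
    "write_csv_dataset",
]

logger = logging.getLogger(__name__)


def default_causal_positions(L: int, n_causal: int = 10) -> list[int]:
    """Evenly spaced block-center positions, scaled to L SNPs.

    For L = 60000 and 10 causal SNPs this reproduces positions
    3000, 9000, ..., 57000 (1-based), i.e. the centers of ten equal blocks.
    """
    block = L / n_causal
    return [int(round(block * k + block / 2)) - 1 for k in range(n_causal)]


def beta_pattern(beta1: float, n_causal: int = 10, base: float = 0.4) -> np.ndarray:
    """(beta1, .4, .4, .4, beta1, .4, .4, .4, beta1, .4)-style effect vector."""
    beta = np.full(n_causal, base)
    beta[::4] = beta1  # positions 0, 4, 8 for the standard 10-SNP design
    return beta


@dataclass
class SimSettings:
    """Settings of one synthetic GWAS dataset."""

    n: int = 328
    L: int = 60000
    n_blocks: int = 10
    rho: float = 0.9
    maf_min: float = 0.01
    causal_positions: list[int] | None = None
    beta: np.ndarray | None = None
    alpha: float = 1.0
    tau: float = 0.1
    sigma2: float = 0.2
    model: str = "mixed"  # mixed | null | linear
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.L % self.n_blocks:
            raise ValueError("L must be divisible by n_blocks")
        if self.model not in ("mixed", "null", "linear"):
            raise ValueError("model must be 'mixed', 'null' or 'linear'")
        if self.model == "null":
            self.causal_positions = []
            self.beta = np.empty(0)
        if self.causal_positions is None:
            self.causal_positions = default_causal_positions(self.L)
        self.causal_positions = [int(p) for p in self.causal_positions]
        if any(p < 0 or p >= self.L for p in self.causal_positions):
            raise ValueError("causal positions must lie in [0, L)")
        if self.beta is None:
            self.beta = beta_pattern(0.4, len(self.causal_positions))
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape[0] != len(self.causal_positions):
            raise ValueError("beta length must match causal_positions")

    @property
    def block_size(self) -> int:
        return self.L // self.n_blocks


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, consumed by the metrics."""

    causal_indicator: np.ndarray  # (L,) 0/1
    beta_true: np.ndarray
    u_true: np.ndarray
    kinship_used: np.ndarray

    @property
    def causal_positions(self) -> np.ndarray:
        return np.flatnonzero(self.causal_indicator)

    def to_json(self, path) -> None:
        payload = {
            "causal_positions": self.causal_positions.tolist(),
            "beta_true": self.beta_true.tolist(),
            "L": int(self.causal_indicator.size),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _threshold_block(z: np.ndarray, mafs: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg thresholding of latent normals into dosages 0/1/2."""
    q = 1.0 - mafs
    t1 = stats.norm.ppf(q**2)  # below: 0 copies of the minor allele
    t2 = stats.norm.ppf(q**2 + 2 * q * mafs)
    return (z >= t1).astype(float) + (z >= t2)


def simulate_genotypes(settings: SimSettings, rng: np.random.Generator | None = None) -> np.ndarray:
    """LD-block dosage matrix of shape (n, L).

    Within each block the latent process is AR(1) with correlation rho;
    columns whose realized MAF falls below ``maf_min`` are re-thresholded
    with a fresh, larger MAF draw so the output always satisfies the MAF
    floor with no constant columns.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    n, bs = settings.n, settings.block_size
    rho = settings.rho
    blocks = []
    for _ in range(settings.n_blocks):
        e = rng.standard_normal((n, bs))
        z = np.empty((n, bs))
        z[:, 0] = e[:, 0]
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, bs):
            z[:, j] = rho * z[:, j - 1] + scale * e[:, j]
        mafs = rng.uniform(settings.maf_min, 0.5, size=bs)
        g = _threshold_block(z, mafs)
        freq = g.mean(axis=0) / 2.0
        bad = np.flatnonzero(np.minimum(freq, 1 - freq) < settings.maf_min)
        tries = 0
        while bad.size and tries < 200:
            mafs[bad] = rng.uniform(max(0.05, settings.maf_min), 0.5, size=bad.size)
            g[:, bad] = _threshold_block(z[:, bad], mafs[bad])
            freq = g.mean(axis=0) / 2.0
            bad = np.flatnonzero(np.minimum(freq, 1 - freq) < settings.maf_min)
            tries += 1
        if bad.size:
            raise RuntimeError("could not satisfy the MAF floor; increase n")
        # ensure minor-allele coding
        flip = freq > 0.5
        g[:, flip] = 2.0 - g[:, flip]
        blocks.append(g)
    return np.hstack(blocks)


def build_kinship(G: np.ndarray) -> np.ndarray:
    """VanRaden realized-relationship matrix from dosages.

    W = G - 2 p (column-centered at twice the allele frequency),
    K = W W' / (2 sum_j p_j (1 - p_j)), symmetrized and eigenvalue-clipped
    at zero.  Monomorphic columns carry no relationship information and
    are excluded with a warning.
    """
    G = np.asarray(G, dtype=float)
    p = G.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic column(s) excluded from kinship",
            stacklevel=2,
        )
        G, p = G[:, poly], p[poly]
    W = G - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    K = (W @ W.T) / denom
    K = 0.5 * (K + K.T)
    ev, U = np.linalg.eigh(K)
    if ev.min() < 0:
        K = (U * np.clip(ev, 0.0, None)) @ U.T
        K = 0.5 * (K + K.T)
    return K


def simulate_phenotype(
    G: np.ndarray,
    K: np.ndarray,
    settings: SimSettings,
    rng: np.random.Generator | None = None,
    Z: np.ndarray | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Phenotype vector plus ground truth under the chosen model variant.

    ``mixed``: Y = alpha 1 + G beta + Z u + eps;
    ``null``: the same without genetic effects;
    ``linear``: the same without the random effect u.
    ``Z`` defaults to the identity (one observation per strain).
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed + 1)
    n = G.shape[0]
    L = G.shape[1]
    if Z is None:
        Z = np.eye(n)
    t = Z.shape[1]
    y = np.full(n, settings.alpha)
    beta_full = np.zeros(L)
    indicator = np.zeros(L, dtype=int)
    if settings.model != "null" and len(settings.causal_positions):
        beta_full[settings.causal_positions] = settings.beta
        indicator[settings.causal_positions] = 1
        y = y + G[:, settings.causal_positions] @ settings.beta
    if settings.model in ("mixed", "null"):
        ev, U = np.linalg.eigh(0.5 * (K + K.T))
        u = U @ (np.sqrt(np.clip(ev, 0.0, None) * settings.sigma2 * settings.tau)
                 * rng.standard_normal(t))
        y = y + Z @ u
    else:
        u = np.zeros(t)
    y = y + rng.standard_normal(n) * np.sqrt(settings.sigma2)
    truth = SimTruth(
        causal_indicator=indicator,
        beta_true=settings.beta.copy(),
        u_true=u,
        kinship_used=K,
    )
    return y, truth


def simulate_dataset(settings: SimSettings, rng: np.random.Generator | None = None):
    """Convenience wrapper: genotypes, kinship, phenotype, truth.

    Returns ``(G, K, Y, truth)``.  Kinship is built from the simulated
    genotypes themselves.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    G = simulate_genotypes(settings, rng)
    K = build_kinship(G)
    Y, truth = simulate_phenotype(G, K, settings, rng)
    return G, K, Y, truth


# --- writers ---------------------------------------------------------------

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
_CODE = {0: 0b11, 1: 0b10, 2: 0b00}  # dosage -> 2-bit genotype, SNP-major


def write_plink(G: np.ndarray, prefix, sample_ids=None, snp_ids=None) -> None:
    """Write dosages to PLINK .bed/.bim/.fam (SNP-major, no missing calls)."""
    G = np.asarray(G)
    n, L = G.shape
    prefix = Path(prefix)
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(n)]
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(L)]
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        nbytes = (n + 3) // 4
        for j in range(L):
            packed = bytearray(nbytes)
            col = G[:, j].astype(int)
            for i in range(n):
                packed[i // 4] |= _CODE[int(col[i])] << (2 * (i % 4))
            fh.write(bytes(packed))
    bim = pd.DataFrame(
        {"chrom": 1, "snp_id": snp_ids, "cm": 0, "pos": np.arange(1, L + 1),
         "a1": "A", "a2": "T"}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": sample_ids, "iid": sample_ids, "pat": 0, "mat": 0, "sex": 0,
         "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def write_csv_dataset(out_dir, G, Y, K=None, truth: SimTruth | None = None,
                      sample_ids=None, snp_ids=None) -> None:
    """Write genotypes (CSV), phenotype (2-column TSV), kinship (CSV), truth (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n, L = np.asarray(G).shape
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(n)]
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(L)]
    pd.DataFrame(np.asarray(G, dtype=int), index=sample_ids, columns=snp_ids).to_csv(
        out / "genotypes.csv", index_label="id"
    )
    pd.DataFrame({"id": sample_ids, "phenotype": np.asarray(Y)}).to_csv(
        out / "phenotype.tsv", sep="\t", index=False
    )
    if K is not None:
        pd.DataFrame(np.asarray(K), index=sample_ids, columns=sample_ids).to_csv(
            out / "kinship.csv", index_label="id"
        )
    if truth is not None:
        truth.to_json(out / "truth.json")
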