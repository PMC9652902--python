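"""Readers and writers for analysis inputs.

Genotypes are accepted as PLINK .bed/.bim/.fam triples or as CSV with
individuals in rows (first column the individual ID) and SNPs in columns,
coded as minor-allele dosages 0/1/2 with missing values allowed.  The
phenotype is a two-column TSV keyed by individual ID; kinship and
covariates are optional CSV/TSV files keyed the same way.  Individuals are
aligned by ID intersection in genotype-file order; missing dosages are
mean-imputed per SNP and SNPs at or below the MAF threshold are dropped.

The minimal PLINK codec here handles the standard SNP-major 2-bit .bed
layout (00 = two minor alleles, 10 = het, 11 = zero, 01 = missing).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GWASData, maf_filter

__all__ = ["read_inputs", "read_plink", "read_genotype_csv"]

logger = logging.getLogger(__name__)

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of the A1 (minor) allele; 1 flags a missing call
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a .bed/.bim/.fam triple; returns (dosages, snp table, sample ids).

    Dosages count the A1 allele; missing calls are NaN.
    """
    prefix = Path(str(prefix).removesuffix(".bed"))
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    n, L = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _PLINK_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file")
    nbytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != nbytes * L:
        raise ValueError(".bed payload size does not match .bim/.fam dimensions")
    body = body.reshape(L, nbytes)
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts) & 0b11  # (L, nbytes, 4)
    codes = codes.reshape(L, nbytes * 4)[:, :n]
    G = _DECODE[codes].T  # (n, L)
    snp_ids = bim[["snp_id", "chrom", "pos"]].copy()
    return G, snp_ids, fam["iid"].astype(str).tolist()


def read_genotype_csv(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read an individuals x SNPs dosage CSV (first column = individual ID)."""
    df = pd.read_csv(path, index_col=0)
    G = df.to_numpy(dtype=float)
    vals = G[~np.isnan(G)]
    if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
        raise ValueError("genotype CSV contains codes outside {0, 1, 2, missing}")
    snp_ids = pd.DataFrame(
        {"snp_id": df.columns, "chrom": 0, "pos": np.arange(1, df.shape[1] + 1)}
    )
    return G, snp_ids, df.index.astype(str).tolist()


def read_inputs(
    geno_path,
    pheno_path,
    kinship_path=None,
    covar_path=None,
    maf: float = 0.01,
    log_pheno: bool = False,
) -> GWASData:
    """Load and align all analysis inputs into a validated GWASData.

    Sample order follows the genotype file restricted to IDs present in
    the phenotype file.  SNPs with minor allele frequency <= ``maf`` are
    removed (count logged); missing dosages are mean-imputed per SNP.
    With ``log_pheno`` the natural log of the phenotype is analyzed.
    """
    geno_path = Path(geno_path)
    if geno_path.suffix == ".bed" or geno_path.with_suffix(".bed").exists():
        G, snp_ids, geno_ids = read_plink(geno_path)
    else:
        G, snp_ids, geno_ids = read_genotype_csv(geno_path)

    pheno = pd.read_csv(pheno_path, sep="\t")
    pheno.columns = ["id", "phenotype", *pheno.columns[2:]]
    pheno["id"] = pheno["id"].astype(str)
    pheno = pheno.set_index("id")["phenotype"]
    common = [i for i in geno_ids if i in pheno.index]
    if not common:
        raise ValueError("no overlapping individual IDs between genotype and phenotype")
    rows = [geno_ids.index(i) for i in common]
    G = G[rows]
    Y = pheno.loc[common].to_numpy(dtype=float)
    if log_pheno:
        Y = np.log(Y)

    # impute missing dosages with the column mean
    miss = np.isnan(G)
    if miss.any():
        logger.info("mean-imputing %d missing dosage calls", int(miss.sum()))
        means = np.nanmean(G, axis=0)
        G[miss] = np.take(means, np.nonzero(miss)[1])

    keep, drop = maf_filter(G, maf)
    if drop.size:
        logger.info("MAF filter removed %d of %d SNPs", drop.size, G.shape[1])
    G = G[:, keep]
    snp_ids = snp_ids.iloc[keep].reset_index(drop=True)

    X_cov = np.ones((len(common), 1))
    if covar_path is not None:
        cov = pd.read_csv(covar_path, sep="\t")
        cov.columns = ["id", *cov.columns[1:]]
        cov["id"] = cov["id"].astype(str)
        cov = cov.set_index("id").loc[common]
        X_cov = np.hstack([X_cov, cov.to_numpy(dtype=float)])

    K = None
    if kinship_path is not None:
        kdf = pd.read_csv(kinship_path, index_col=0)
        kdf.index = kdf.index.astype(str)
        kdf.columns = kdf.columns.astype(str)
        K = kdf.loc[common, common].to_numpy(dtype=float)
    else:
        from .simulate import build_kinship

        K = build_kinship(G)

    return GWASData(
        Y=Y, G=G, X_cov=X_cov, K=K, snp_ids=snp_ids,
        sample_ids=np.asarray(common),
    )
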