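"""Bayesian model selection over the base ∪ candidate SNP union.

With the kinship dependence parameter tau fixed once from the full model
(P3D), every candidate model is a weighted least squares fit in the rotated
eigenbasis, so model scores reduce to solves against submatrices of a
single precomputed Gram matrix — no per-model O(n) work.

Model spaces with fewer than 16 SNPs are enumerated completely; larger
spaces are searched with a genetic algorithm over binary inclusion
chromosomes (population 100; initialized with the intercept-only model, up
to 99 single-SNP models ranked by screening posterior, and random
chromosomes; fitness-proportional selection with weights
exp(-0.5 * score); single-point crossover; one-bit mutation; elitism).
The default score is the prior-adjusted BIC, score = BIC - 2 log P(M), so
the GA maximizes the same posterior that enumeration ranks by; plain-BIC
fitness is available via :class:`GAConfig`.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data import GWASData
from .lmm import LOG2PI, SpectralBasis, eigen_rotate, fit_lmm
from .posterior import ModelPrior, prior_model_prob

__all__ = ["GAConfig", "SearchResult", "p3d_tau", "enumerate_models", "ga_search"]

logger = logging.getLogger(__name__)

ENUM_LIMIT = 15  # complete enumeration up to this many SNPs; GA at 16+


@dataclass
class GAConfig:
    """Genetic-algorithm settings (defaults: population 100, stop after 400
    generations or 40 consecutive generations with the same best model;
    the 4000/400 convergence pair can be requested here as well)."""

    pop_size: int = 100
    max_iter: int = 400
    run_stop: int = 40
    p_mutation: float = 0.1
    p_crossover: float = 0.8
    seed: int = 0
    fitness: str = "prior_adjusted"  # or "bic"

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.run_stop > self.max_iter:
            raise ValueError("run_stop must not exceed max_iter")
        if self.fitness not in ("prior_adjusted", "bic"):
            raise ValueError("fitness must be 'prior_adjusted' or 'bic'")


@dataclass
class ScoredModel:
    snps: tuple[int, ...]  # data SNP indices, sorted
    bic: float
    log_prior: float

    @property
    def score(self) -> float:
        return self.bic - 2.0 * self.log_prior


@dataclass
class SearchResult:
    best: ScoredModel
    best_posterior: float  # posterior of the best among all scored models
    scored_models: dict[tuple[int, ...], ScoredModel]
    method: str  # "enumeration" | "ga"
    tau_p3d: float
    converged_at: int | None = None  # GA generation of last improvement
    cache_hits: int = 0
    best_trajectory: list[float] | None = None  # GA best score per generation


class _ModelScorer:
    """Scores arbitrary subsets of a fixed SNP union at a fixed tau.

    Precomputes the rotated design Gram matrix once; each model evaluation
    is then a dense solve of size (c + p_i).
    """

    def __init__(
        self,
        data: GWASData,
        union_snps,
        prior: ModelPrior,
        tau: float,
        basis: SpectralBasis | None = None,
    ):
        self.union = tuple(int(s) for s in union_snps)
        self.prior = prior.with_s(len(self.union))
        self.tau = float(tau)
        if basis is None:
            basis = eigen_rotate(data.Z, data.K)
        n = data.n
        w = 1.0 / (1.0 + self.tau * basis.lambdas)
        T = np.hstack([data.X_cov, data.G[:, list(self.union)]]) if self.union else data.X_cov
        Tt = basis.rotate(T)
        yt = basis.rotate(data.Y)
        Tw = Tt * w[:, None]
        self.c = data.c
        self.n = n
        self.gram = Tt.T @ Tw
        self.b = Tw.T @ yt
        self.syy = float(yt @ (w * yt))
        self.logdet = float(np.log1p(self.tau * basis.lambdas).sum())
        self.cache: dict[tuple[int, ...], ScoredModel] = {}
        self.cache_hits = 0

    def score_positions(self, positions: tuple[int, ...]) -> ScoredModel:
        """Score the model containing the union SNPs at these positions."""
        key = tuple(sorted(positions))
        hit = self.cache.get(key)
        if hit is not None:
            self.cache_hits += 1
            return hit
        cols = list(range(self.c)) + [self.c + p for p in key]
        A = self.gram[np.ix_(cols, cols)]
        bb = self.b[cols]
        beta = np.linalg.solve(A, bb)
        rss = max(self.syy - float(bb @ beta), 1e-300)
        sigma2 = rss / self.n
        ll = -0.5 * (self.n * (LOG2PI + math.log(sigma2)) + self.logdet + self.n)
        d = len(cols) + 2
        bic = -2.0 * ll + d * math.log(self.n)
        lp = prior_model_prob(self.prior, len(key))
        sm = ScoredModel(
            snps=tuple(self.union[p] for p in key), bic=bic, log_prior=lp
        )
        self.cache[key] = sm
        return sm

    def posterior_of(self, model: ScoredModel) -> float:
        logw = np.array(
            [m.log_prior - 0.5 * m.bic for m in self.cache.values()]
        )
        return float(
            math.exp(model.log_prior - 0.5 * model.bic - logsumexp(logw))
        )


def p3d_tau(
    data: GWASData,
    union_snps,
    basis: SpectralBasis | None = None,
) -> float:
    """Kinship dependence parameter estimated once from the full model.

    The full model contains every SNP in the union; its ML tau_hat is then
    held fixed for all model fits of the selection step.  If the full
    design is too large or rank-deficient the base (covariate-only) model's
    tau_hat is used instead.
    """
    union = sorted(int(s) for s in union_snps)
    if data.c + len(union) > data.n - 2:
        logger.warning("full model too large for n=%d; tau from base model", data.n)
        return fit_lmm(data, (), basis=basis).tau_hat
    try:
        return fit_lmm(data, union, basis=basis).tau_hat
    except ValueError as e:
        logger.warning("full-model fit failed (%s); tau from base model", e)
        return fit_lmm(data, (), basis=basis).tau_hat


def _better(a: ScoredModel, b: ScoredModel) -> bool:
    """True if a strictly beats b: lower score, then fewer SNPs, then lex."""
    if a.score < b.score - 1e-12:
        return True
    if a.score > b.score + 1e-12:
        return False
    return (len(a.snps), a.snps) < (len(b.snps), b.snps)


def enumerate_models(
    data: GWASData,
    base_snps,
    candidates,
    prior: ModelPrior,
    tau_p3d: float,
    basis: SpectralBasis | None = None,
) -> SearchResult:
    """Score every subset of base ∪ candidate SNPs; return the best model.

    Base SNPs are droppable: the space is all 2^s combinations of the
    union.  Refuses spaces larger than 2^15, where the GA takes over.
    """
    union = sorted(set(int(s) for s in base_snps) | set(int(s) for s in candidates))
    s = len(union)
    if s > ENUM_LIMIT:
        raise ValueError(
            f"model space of {s} SNPs exceeds the enumeration limit "
            f"({ENUM_LIMIT}); use ga_search"
        )
    scorer = _ModelScorer(data, union, prior, tau_p3d, basis)
    best = scorer.score_positions(())
    for p in range(1, s + 1):
        for combo in itertools.combinations(range(s), p):
            sm = scorer.score_positions(combo)
            if _better(sm, best):
                best = sm
    return SearchResult(
        best=best,
        best_posterior=scorer.posterior_of(best),
        scored_models={m.snps: m for m in scorer.cache.values()},
        method="enumeration",
        tau_p3d=tau_p3d,
        cache_hits=scorer.cache_hits,
    )


def ga_search(
    data: GWASData,
    base_snps,
    candidates,
    prior: ModelPrior,
    tau_p3d: float,
    cfg: GAConfig | None = None,
    screening_posteriors: np.ndarray | None = None,
    basis: SpectralBasis | None = None,
) -> SearchResult:
    """Genetic-algorithm search of the model space over the SNP union.

    ``screening_posteriors``, when given as a length-L vector, ranks the
    union SNPs for the single-SNP seeding of the initial population.
    Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    union = sorted(set(int(s) for s in base_snps) | set(int(s) for s in candidates))
    s = len(union)
    scorer = _ModelScorer(data, union, prior, tau_p3d, basis)
    if s == 0:
        best = scorer.score_positions(())
        return SearchResult(
            best=best, best_posterior=1.0,
            scored_models={best.snps: best}, method="ga", tau_p3d=tau_p3d,
            converged_at=0,
        )

    def evaluate(chrom: np.ndarray) -> ScoredModel:
        return scorer.score_positions(tuple(np.flatnonzero(chrom)))

    # --- initial population: intercept-only, top single-SNP models, random
    pop = [np.zeros(s, dtype=bool)]
    if screening_posteriors is not None:
        rank = np.argsort(
            [-screening_posteriors[g] if np.isfinite(screening_posteriors[g]) else np.inf
             for g in union]
        )
    else:
        rank = np.arange(s)
    for p in rank[: min(s, 99)]:
        chrom = np.zeros(s, dtype=bool)
        chrom[p] = True
        pop.append(chrom)
    while len(pop) < cfg.pop_size:
        pop.append(rng.random(s) < 0.5)
    pop = pop[: cfg.pop_size]

    scores = np.array([_fitness_score(evaluate(c), cfg) for c in pop])
    best = evaluate(pop[int(np.argmin(scores))])
    stable = 0
    last_improve = 0
    trajectory = [best.score]
    for gen in range(1, cfg.max_iter + 1):
        # selection: probabilities proportional to exp(-0.5 * score)
        logw = -0.5 * scores
        probs = np.exp(logw - logsumexp(logw))
        idx = rng.choice(len(pop), size=cfg.pop_size, p=probs)
        parents = [pop[i].copy() for i in idx]
        children = []
        for a, b in zip(parents[0::2], parents[1::2]):
            if s > 1 and rng.random() < cfg.p_crossover:
                cut = int(rng.integers(1, s))
                a2 = np.concatenate([a[:cut], b[cut:]])
                b2 = np.concatenate([b[:cut], a[cut:]])
                a, b = a2, b2
            children.extend([a, b])
        if len(children) < cfg.pop_size:
            children.append(parents[-1])
        for c in children:
            if rng.random() < cfg.p_mutation:
                c[int(rng.integers(s))] ^= True
        # elitism: best-so-far replaces the worst child
        ch_scores = np.array([_fitness_score(evaluate(c), cfg) for c in children])
        worst = int(np.argmax(ch_scores))
        elite = np.zeros(s, dtype=bool)
        elite[[union.index(g) for g in best.snps]] = True
        children[worst] = elite
        ch_scores[worst] = _fitness_score(evaluate(elite), cfg)
        pop, scores = children, ch_scores

        gen_best = evaluate(pop[int(np.argmin(scores))])
        if _better(gen_best, best):
            best = gen_best
            stable = 0
            last_improve = gen
        else:
            stable += 1
        trajectory.append(best.score)
        if stable >= cfg.run_stop:
            break
    logger.info("GA converged at generation %d (best stable for %d)", last_improve, stable)
    return SearchResult(
        best=best,
        best_posterior=scorer.posterior_of(best),
        scored_models={m.snps: m for m in scorer.cache.values()},
        method="ga",
        tau_p3d=tau_p3d,
        converged_at=last_improve,
        cache_hits=scorer.cache_hits,
        best_trajectory=trajectory,
    )


def _fitness_score(sm: ScoredModel, cfg: GAConfig) -> float:
    return sm.score if cfg.fitness == "prior_adjusted" else sm.bic
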