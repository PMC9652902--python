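"""The BICOSS outer loop: screen, select, repeat until the best model fixes.

Each iteration fits the current base model (covariates plus base SNPs) by
ML, screens every remaining SNP against the base-model residuals with
Bayesian FDR control, and then searches the space spanned by the base and
candidate SNPs — complete enumeration up to 15 SNPs, genetic algorithm
beyond.  The best model becomes the next base model; the procedure stops
when the best model equals its base model (fixed point), when a base model
repeats (cycle — a safeguard, since the underlying procedure assumes
convergence), or after ``max_outer`` iterations.

The null-proportion pi0 is re-estimated at every screening step from the
whitened Wald p-values, but every selection step reuses the pi0 of the
first screening, which keeps early-discovered SNPs competitive against
SNPs surfacing in later conditional screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import GWASData, find_aliases
from .lmm import LMMFit, eigen_rotate, fit_lmm, residualize
from .posterior import ModelPrior, SNPModel, estimate_pi0, prior_model_prob, snp_posterior
from .screening import bayesian_fdr_select, screen_snps
from .search import ENUM_LIMIT, GAConfig, SearchResult, enumerate_models, ga_search, p3d_tau

__all__ = ["BicossRun", "IterationRecord", "run_bicoss"]

logger = logging.getLogger(__name__)


@dataclass
class IterationRecord:
    base_snps: tuple[int, ...]
    candidates: tuple[int, ...]
    best_snps: tuple[int, ...]
    tau_hat: float
    pi0: float
    search_method: str
    best_score: float  # BIC - 2 log prior under the frozen pi0


@dataclass
class BicossRun:
    iterations: list[IterationRecord]
    final_model: SNPModel
    final_fit: LMMFit
    converged: bool
    stop_reason: str  # fixed_point | cycle | max_iter
    aliases: dict[int, list[int]] = field(default_factory=dict)
    snp_iteration: dict[int, int] = field(default_factory=dict)
    pi0_first: float = float("nan")

    @property
    def selected(self) -> tuple[int, ...]:
        return self.final_model.snps


def run_bicoss(
    data: GWASData,
    q0: float = 0.05,
    ga_cfg: GAConfig | None = None,
    max_outer: int = 50,
    seed: int = 0,
) -> BicossRun:
    """Run the full iterative screen/select procedure on one dataset.

    Parameters
    ----------
    q0 : nominal Bayesian FDR level of each screening step.
    ga_cfg : genetic-algorithm settings for model spaces of 16+ SNPs;
        ``ga_cfg.seed`` is re-derived per iteration from ``seed``.
    max_outer : hard cap on outer iterations.
    seed : master seed controlling all stochastic search.

    Returns a :class:`BicossRun` with per-iteration provenance.
    """
    basis = eigen_rotate(data.Z, data.K)
    base: frozenset[int] = frozenset()
    seen_bases = {base}
    frozen_prior: ModelPrior | None = None
    records: list[IterationRecord] = []
    best_by_model: dict[frozenset[int], SearchResult] = {}
    snp_iteration: dict[int, int] = {}
    aliases_all: dict[int, list[int]] = {}
    stop_reason = "max_iter"
    converged = False
    ga_cfg = ga_cfg or GAConfig()

    for it in range(max_outer):
        fit = fit_lmm(data, sorted(base), basis=basis)
        yhat, sigma = residualize(data, fit, basis=basis)
        screen = screen_snps(yhat, sigma, data.G, base_snps=base)
        prior = estimate_pi0(screen.pvals, data.L)
        if frozen_prior is None:
            frozen_prior = prior
        screen.prior_used = prior
        valid = ~np.isnan(screen.log_bf)
        screen.p_post[valid] = snp_posterior(screen.log_bf[valid], prior, log=True)
        candidates, fdr_curve = bayesian_fdr_select(screen.p_post, q0)
        screen.candidates, screen.fdr_curve, screen.q0 = candidates, fdr_curve, q0
        logger.info(
            "iteration %d: pi0=%.5f (%s), %d candidates, base size %d",
            it, prior.pi0, prior.source.value, candidates.size, len(base),
        )

        union_raw = sorted(base | set(int(c) for c in candidates))
        union, aliases = find_aliases(data.G, union_raw)
        for k, v in aliases.items():
            if v:
                aliases_all.setdefault(k, []).extend(
                    x for x in v if x not in aliases_all.get(k, [])
                )

        tau = p3d_tau(data, union, basis=basis)
        if len(union) <= ENUM_LIMIT:
            result = enumerate_models(data, base, union, frozen_prior, tau, basis=basis)
        else:
            cfg = GAConfig(
                pop_size=ga_cfg.pop_size, max_iter=ga_cfg.max_iter,
                run_stop=ga_cfg.run_stop, p_mutation=ga_cfg.p_mutation,
                p_crossover=ga_cfg.p_crossover,
                seed=(seed * 1000003 + it) % (2**31),
                fitness=ga_cfg.fitness,
            )
            result = ga_search(
                data, base, union, frozen_prior, tau, cfg=cfg,
                screening_posteriors=screen.p_post, basis=basis,
            )
        best = frozenset(result.best.snps)
        best_by_model[best] = result
        for s in best:
            snp_iteration.setdefault(int(s), it)
        records.append(
            IterationRecord(
                base_snps=tuple(sorted(base)),
                candidates=tuple(int(c) for c in candidates),
                best_snps=tuple(sorted(best)),
                tau_hat=tau,
                pi0=prior.pi0,
                search_method=result.method,
                best_score=result.best.score,
            )
        )

        if best == base:
            converged, stop_reason = True, "fixed_point"
            break
        if best in seen_bases:
            stop_reason = "cycle"
            # among the visited best models, return the one with the best
            # prior-adjusted ML score (refit with its own tau)
            scored = []
            for model, res in best_by_model.items():
                f = fit_lmm(data, sorted(model), basis=basis)
                pr = frozen_prior.with_s(max(frozen_prior.s, len(model)))
                scored.append((f.bic - 2.0 * prior_model_prob(pr, len(model)), model))
            scored.sort(key=lambda t: (t[0], len(t[1]), tuple(sorted(t[1]))))
            base = scored[0][1]
            break
        seen_bases.add(best)
        base = best
    else:
        base = frozenset(records[-1].best_snps) if records else base

    final_set = base
    final_fit = fit_lmm(data, sorted(final_set), basis=basis)
    res = best_by_model.get(final_set)
    posterior = res.best_posterior if res is not None else float("nan")
    pr = (frozen_prior or ModelPrior(pi0=1 - 100 / max(data.L, 101), s=data.L)).with_s(
        max(len(final_set), frozen_prior.s if frozen_prior else data.L)
    )
    final_model = SNPModel(
        snps=tuple(sorted(final_set)),
        bic=final_fit.bic,
        bf_vs_base=float("nan"),
        log_prior=prior_model_prob(pr, len(final_set)),
        posterior=posterior,
    )
    return BicossRun(
        iterations=records,
        final_model=final_model,
        final_fit=final_fit,
        converged=converged,
        stop_reason=stop_reason,
        aliases=aliases_all,
        snp_iteration=snp_iteration,
        pi0_first=frozen_prior.pi0 if frozen_prior else float("nan"),
    )
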