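"""Model selection: P3D tau, complete enumeration, genetic algorithm."""

import numpy as np
import pytest

from bicoss import GWASData, ModelPrior, SimSettings, simulate_dataset
from bicoss.lmm import fit_lmm
from bicoss.posterior import bayes_factor_approx, snp_posterior
from bicoss.search import GAConfig, enumerate_models, ga_search, p3d_tau

from conftest import make_dataset


class TestP3DTau:
    def test_empty_union_is_base_model_tau(self, small_data):
        data, _ = small_data
        assert p3d_tau(data, ()) == fit_lmm(data, ()).tau_hat

    def test_invariant_to_snp_ordering(self, small_data):
        data, _ = small_data
        assert p3d_tau(data, (3, 10, 50)) == p3d_tau(data, (50, 3, 10))

    def test_near_zero_under_no_kinship(self):
        """Simulated with tau = 0 and identity kinship, the P3D estimate
        should sit at (or very near) the lower search bound."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 120
            G = rng.integers(0, 3, (n, 8)).astype(float)
            for j in range(8):
                if G[:, j].std() == 0:
                    G[0, j] = (G[0, j] + 1) % 3
            Y = 1.0 + rng.standard_normal(n) * np.sqrt(0.2)
            data = GWASData(Y=Y, G=G, K=np.eye(n))
            hits += p3d_tau(data, (0, 1, 2)) <= 0.05
        assert hits >= 45

    def test_oversized_union_falls_back_to_base(self, caplog):
        data, _ = make_dataset(seed=1, n=30, L=60)
        tau = p3d_tau(data, tuple(range(40)))
        assert tau == fit_lmm(data, ()).tau_hat


class TestEnumeration:
    def test_empty_space_returns_intercept_model(self, small_data):
        data, _ = small_data
        res = enumerate_models(data, (), (), ModelPrior(0.9, 10), tau_p3d=0.1)
        assert res.best.snps == ()
        assert res.method == "enumeration"

    def test_single_snp_decision_matches_two_model_posterior(self, small_data):
        data, _ = small_data
        prior = ModelPrior(0.99, 1)
        tau = p3d_tau(data, (10,))
        res = enumerate_models(data, (), (10,), prior, tau)
        m0 = res.scored_models[()]
        m1 = res.scored_models[(10,)]
        bf = bayes_factor_approx(m1.bic, m0.bic)
        post1 = snp_posterior(bf, prior)
        assert (res.best.snps == (10,)) == (post1 > 0.5)

    def test_refuses_oversized_space(self, small_data):
        data, _ = small_data
        with pytest.raises(ValueError, match="enumeration limit"):
            enumerate_models(data, (), tuple(range(16)), ModelPrior(0.9, 16), 0.1)

    def test_recovers_causal_pair_among_candidates(self):
        hits = 0
        for seed in range(50):
            data, truth = make_dataset(
                seed=seed + 1000, n=300, L=60, causal=[5, 40], beta=[0.8, 0.8],
            )
            candidates = (2, 5, 17, 30, 40, 55)
            prior = ModelPrior(1 - 100 / 2000, len(candidates))
            tau = p3d_tau(data, candidates)
            res = enumerate_models(data, (), candidates, prior, tau)
            hits += res.best.snps == (5, 40)
        assert hits >= 45

    def test_no_model_scored_twice(self, small_data):
        data, _ = small_data
        res = enumerate_models(data, (1, 2), (2, 3, 4), ModelPrior(0.9, 10), 0.1)
        assert res.cache_hits == 0
        assert len(res.scored_models) == 2**4  # union {1,2,3,4}


class TestGA:
    def _instance(self, seed, s=12):
        causal = [3, s - 3]
        data, _ = make_dataset(
            seed=seed, n=200, L=max(40, s + 5), causal=causal, beta=[0.9, 0.7],
        )
        union = tuple(range(s))
        prior = ModelPrior(1 - 100 / 2000, s)
        tau = p3d_tau(data, union)
        return data, union, prior, tau

    def test_matches_enumeration_on_small_spaces(self):
        agree = 0
        for seed in range(10):
            data, union, prior, tau = self._instance(seed + 50, s=10)
            enum = enumerate_models(data, (), union, prior, tau)
            ga = ga_search(data, (), union, prior, tau, cfg=GAConfig(seed=seed))
            agree += ga.best.snps == enum.best.snps
        assert agree == 10

    def test_seeded_determinism(self):
        data, union, prior, tau = self._instance(99, s=10)
        cfg = GAConfig(seed=7)
        a = ga_search(data, (), union, prior, tau, cfg=cfg)
        b = ga_search(data, (), union, prior, tau, cfg=cfg)
        assert a.best.snps == b.best.snps
        assert a.best.bic == b.best.bic
        assert a.best_trajectory == b.best_trajectory
        assert sorted(a.scored_models) == sorted(b.scored_models)

    def test_best_score_monotone_under_elitism(self):
        data, union, prior, tau = self._instance(123, s=12)
        res = ga_search(data, (), union, prior, tau, cfg=GAConfig(seed=3))
        traj = np.array(res.best_trajectory)
        assert np.all(np.diff(traj) <= 1e-12)

    def test_cache_prevents_reevaluation(self):
        data, union, prior, tau = self._instance(5, s=10)
        res = ga_search(data, (), union, prior, tau, cfg=GAConfig(seed=1))
        # far more chromosome evaluations than distinct models
        assert res.cache_hits > 0
        assert len(res.scored_models) <= 2 ** len(union)

    def test_bic_only_fitness_mode_runs(self):
        data, union, prior, tau = self._instance(6, s=10)
        res = ga_search(data, (), union, prior, tau,
                        cfg=GAConfig(seed=1, fitness="bic"))
        assert res.method == "ga"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(pop_size=1)
        with pytest.raises(ValueError):
            GAConfig(run_stop=500, max_iter=400)
        with pytest.raises(ValueError):
            GAConfig(fitness="nope")
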