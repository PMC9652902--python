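"""Metrics arithmetic, file I/O round trips, experiment harness, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from bicoss import score_discoveries
from bicoss.cli import main as cli_main
from bicoss.experiment import replicate_seeds, run_experiment
from bicoss.io import read_genotype_csv, read_inputs, read_plink
from bicoss.metrics import MetricsReport
from bicoss.simulate import SimSettings, SimTruth, simulate_dataset, write_plink


def _truth(L, causal):
    ind = np.zeros(L, dtype=int)
    ind[list(causal)] = 1
    return SimTruth(
        causal_indicator=ind, beta_true=np.ones(len(causal)),
        u_true=np.zeros(3), kinship_used=np.eye(3),
    )


class TestMetrics:
    def test_perfect_recovery(self):
        truth = _truth(100, range(10))
        rep = score_discoveries(range(10), truth)
        assert (rep.recall, rep.fdr, rep.f1) == (1.0, 0.0, 1.0)

    def test_printed_definition_arithmetic(self):
        truth = _truth(100, range(10))
        found = list(range(7)) + [90, 91, 92]  # tp=7 fp=3 fn=3
        rep = score_discoveries(found, truth)
        assert np.isclose(rep.recall, 0.7)
        assert np.isclose(rep.fdr, 0.3)
        assert np.isclose(rep.f1, 0.7)

    def test_empty_discovery_zero_conventions(self):
        rep = score_discoveries([], _truth(50, [1, 2]))
        assert (rep.recall, rep.fdr, rep.fpr, rep.f1) == (0.0, 0.0, 0.0, 0.0)

    def test_identities_on_random_confusions(self, rng):
        for _ in range(200):
            L = int(rng.integers(20, 100))
            k = int(rng.integers(0, 10))
            causal = rng.choice(L, size=k, replace=False)
            found = rng.choice(L, size=int(rng.integers(0, 15)), replace=False)
            rep = score_discoveries(found, _truth(L, causal))
            assert rep.tp + rep.fn == k
            assert rep.tp + rep.fp == len(set(found.tolist()))
            assert rep.tp + rep.fp + rep.fn + rep.tn == L
            if rep.tp + rep.fp:
                assert np.isclose(rep.fdr, rep.fp / (rep.tp + rep.fp))

    def test_ld_neighbor_counts_as_fp_by_default(self):
        truth = _truth(100, [50])
        strict = score_discoveries([51], truth)
        assert strict.tp == 0 and strict.fp == 1
        windowed = score_discoveries([51], truth, window=2)
        assert windowed.fp == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_discoveries([200], _truth(100, [5]))


class TestIO:
    def _toy_csv(self, tmp_path, ids=("a", "b", "c", "d", "e")):
        G = pd.DataFrame(
            {
                "s1": [0, 1, 2, 1, 0],
                "s2": [0, 0, 0, 0, 0],  # MAF 0, must be dropped
                "s3": [2, 1, 0, 1, 2],
                "s4": [1, 1, 0, 2, 1],
            },
            index=list(ids),
        )
        path = tmp_path / "geno.csv"
        G.to_csv(path, index_label="id")
        pheno = pd.DataFrame({"id": list(ids), "phenotype": [0.1, 1.2, 2.1, 1.1, 0.3]})
        ppath = tmp_path / "pheno.tsv"
        pheno.to_csv(ppath, sep="\t", index=False)
        return path, ppath

    def test_maf_zero_column_dropped(self, tmp_path):
        gpath, ppath = self._toy_csv(tmp_path)
        data = read_inputs(gpath, ppath)
        assert data.L == 3
        assert data.snp_ids["snp_id"].tolist() == ["s1", "s3", "s4"]

    def test_plink_csv_round_trip(self, tmp_path):
        s = SimSettings(n=12, L=20, n_blocks=2, seed=3, causal_positions=[], beta=[])
        G, K, Y, _ = simulate_dataset(s)
        write_plink(G, tmp_path / "toy")
        G2, snps, ids = read_plink(tmp_path / "toy")
        assert np.array_equal(G, G2)
        assert len(ids) == 12 and len(snps) == 20

    def test_permuted_phenotype_order_aligned(self, tmp_path):
        gpath, ppath = self._toy_csv(tmp_path)
        shuffled = pd.read_csv(ppath, sep="\t").iloc[[3, 1, 4, 0, 2]]
        p2 = tmp_path / "pheno2.tsv"
        shuffled.to_csv(p2, sep="\t", index=False)
        a = read_inputs(gpath, ppath)
        b = read_inputs(gpath, p2)
        assert np.array_equal(a.Y, b.Y)
        assert np.array_equal(a.G, b.G)

    def test_empty_id_intersection_rejected(self, tmp_path):
        gpath, _ = self._toy_csv(tmp_path)
        bad = tmp_path / "bad.tsv"
        pd.DataFrame({"id": ["x", "y"], "phenotype": [1.0, 2.0]}).to_csv(
            bad, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="overlapping"):
            read_inputs(gpath, bad)

    def test_bad_genotype_codes_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"s1": [0, 3, 1]}, index=["a", "b", "c"]).to_csv(
            path, index_label="id"
        )
        with pytest.raises(ValueError, match="codes"):
            read_genotype_csv(path)

    def test_missing_dosages_mean_imputed(self, tmp_path):
        path = tmp_path / "m.csv"
        pd.DataFrame(
            {"s1": [0, 1, 2, None, 1], "s2": [1, 0, 1, 2, 1]},
            index=list("abcde"),
        ).to_csv(path, index_label="id")
        pheno = tmp_path / "p.tsv"
        pd.DataFrame({"id": list("abcde"), "phenotype": range(5)}).to_csv(
            pheno, sep="\t", index=False
        )
        data = read_inputs(path, pheno)
        assert np.isclose(data.G[3, 0], 1.0)  # column mean of (0,1,2,1)


class TestExperiment:
    CONFIG = {
        "methods": ["sma-ols", "sma-approx"],
        "settings": {"n": 80, "L": 60, "n_blocks": 2, "rho": 0.0,
                     "causal_positions": [10, 40], "beta": [1.2, 0.9]},
        "n_replicates": 2,
        "seed": 123,
    }

    def test_deterministic_outputs(self, tmp_path):
        run_experiment(self.CONFIG, out_dir=tmp_path / "a")
        run_experiment(self.CONFIG, out_dir=tmp_path / "b")
        for name in ("per_replicate.csv", "metrics.json", "metrics.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_replicate_seeds_below_2_31(self):
        seeds = replicate_seeds(7, 10)
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2**31 for s in seeds)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            run_experiment({**self.CONFIG, "methods": ["lasso"]})

    def test_null_model_reports_fp_only(self, tmp_path):
        cfg = {
            "methods": ["sma-ols"],
            "settings": {"n": 60, "L": 50, "n_blocks": 2, "model": "null"},
            "n_replicates": 2,
            "seed": 5,
        }
        res = run_experiment(cfg, out_dir=tmp_path)
        rep = res["sma-ols"]["report"]
        assert rep.tp == 0 and rep.fn == 0
        assert rep.recall == 0.0  # 0/0 convention


class TestCLI:
    def test_simulate_then_analyze(self, tmp_path):
        runner = CliRunner()
        settings = tmp_path / "settings.yaml"
        settings.write_text(
            "n: 60\nL: 40\nn_blocks: 2\nrho: 0.0\nseed: 4\n"
            "causal_positions: [5]\nbeta: [1.5]\n"
        )
        simdir = tmp_path / "sim"
        r = runner.invoke(cli_main, ["simulate", "--settings", str(settings),
                                     "--out", str(simdir)])
        assert r.exit_code == 0, r.output
        assert (simdir / "genotypes.csv").exists()
        assert json.loads((simdir / "truth.json").read_text())["causal_positions"] == [5]

        outdir = tmp_path / "res"
        r = runner.invoke(cli_main, [
            "run", "--geno", str(simdir / "genotypes.csv"),
            "--pheno", str(simdir / "phenotype.tsv"),
            "--kinship", str(simdir / "kinship.csv"),
            "--method", "sma-ols", "--seed", "1", "--out", str(outdir),
        ])
        assert r.exit_code == 0, r.output
        table = pd.read_csv(outdir / "selected_snps.tsv", sep="\t")
        assert "snp_id" in table.columns

    def test_bicoss_run_writes_trace(self, tmp_path):
        runner = CliRunner()
        simdir = tmp_path / "sim"
        settings = tmp_path / "s.yaml"
        settings.write_text(
            "n: 80\nL: 60\nn_blocks: 2\nrho: 0.0\nseed: 9\n"
            "causal_positions: [20]\nbeta: [2.0]\n"
        )
        runner.invoke(cli_main, ["simulate", "--settings", str(settings),
                                 "--out", str(simdir)])
        outdir = tmp_path / "res"
        r = runner.invoke(cli_main, [
            "run", "--geno", str(simdir / "genotypes.csv"),
            "--pheno", str(simdir / "phenotype.tsv"),
            "--method", "bicoss", "--seed", "1", "--out", str(outdir),
        ])
        assert r.exit_code == 0, r.output
        trace = json.loads((outdir / "trace.json").read_text())
        assert trace["stop_reason"] in ("fixed_point", "cycle", "max_iter")
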