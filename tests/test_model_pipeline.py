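"""Model/Results workflow, pipeline orchestration and the CLI surface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from immunosig.cli import main as cli_main
from immunosig.errors import MissingGeneError
from immunosig.model import SignatureDiscovery, apply_signature
from immunosig.pipeline import PipelineConfig, run_pipeline
from immunosig.signature import load_reference_signature
from immunosig.simulate import SynthConfig, generate_cohort, make_signature_scenario
from immunosig.matrix import housekeeping_normalize


@pytest.fixture(scope="module")
def scenario():
    cfg, coll = make_signature_scenario(n_samples=30, seed=21)
    return generate_cohort(cfg), coll


@pytest.fixture(scope="module")
def fitted(scenario):
    cohort, coll = scenario
    model = SignatureDiscovery(cohort.expression, cohort.annotation, coll,
                               n_permutations=500)
    return model.fit(seed=11)


class TestSignatureDiscovery:
    def test_recovers_planted_core_genes(self, scenario, fitted):
        cohort, _ = scenario
        planted = set(cohort.config.planted_genes)
        assert planted <= set(fitted.signature.core_genes)
        for g in fitted.signature.core_genes:
            assert len(fitted.signature.provenance[g]) >= 2

    def test_top_pathways_are_the_planted_ones(self, fitted):
        assert all(name.startswith("GOBP") for name in fitted.top_pathways)

    def test_results_carry_outcome_layers(self, fitted):
        assert fitted.survival.p < 0.05
        assert fitted.roc.auc > 0.8
        assert fitted.score_test[1] < 0.05
        assert set(fitted.scores.strata.unique()) == {"high", "low"}
        assert fitted.cell_scores["p"].between(0, 1).all()

    def test_summary_prints_key_numbers(self, fitted):
        text = fitted.summary()
        assert "core genes" in text and "log-rank" in text
        assert f"{fitted.roc.auc:.3f}" in text

    def test_apply_scores_independent_cohort(self, fitted):
        cfg2, _ = make_signature_scenario(n_samples=26, seed=77)
        val = generate_cohort(cfg2)
        res = fitted.apply(val.expression, val.annotation)
        assert res.scores.scores.size == 26
        assert res.roc is not None and res.roc.auc > 0.7
        assert "Signature validation" in res.summary()

    def test_apply_never_mutates_the_signature(self, fitted):
        before = list(fitted.signature.core_genes)
        cfg2, _ = make_signature_scenario(n_samples=26, seed=78)
        val = generate_cohort(cfg2)
        fitted.apply(val.expression, val.annotation)
        assert fitted.signature.core_genes == before

    def test_unannotated_sample_rejected_at_construction(self, scenario):
        cohort, coll = scenario
        ann = cohort.annotation.subset(cohort.annotation.sample_ids[:-1])
        with pytest.raises(ValueError):
            SignatureDiscovery(cohort.expression, ann, coll)


class TestApplyFrozenSignature:
    def test_reference_signature_on_synthetic_cohort(self):
        cfg, _ = make_signature_scenario(n_samples=26, seed=5)
        cohort = generate_cohort(cfg)
        values = housekeeping_normalize(cohort.expression)
        res = apply_signature(load_reference_signature(), values, cohort.annotation)
        assert res.roc.auc > 0.7  # planted genes ARE the frozen signature

    def test_missing_signature_gene_is_named(self):
        cohort = generate_cohort(SynthConfig(n_samples=10, seed=1,
                                             include_marker_genes=False))
        values = housekeeping_normalize(cohort.expression)
        with pytest.raises(MissingGeneError, match="LAG3"):
            apply_signature(load_reference_signature(), values, cohort.annotation)


def write_inputs(tmp_path, n_samples=30, seed=3):
    cfg, coll = make_signature_scenario(n_samples=n_samples, seed=seed)
    cohort = generate_cohort(cfg)
    cohort.write(tmp_path)
    from immunosig.gsea import write_gmt

    write_gmt(coll, tmp_path / "gene_sets.gmt")
    return cohort


class TestRunPipeline:
    def test_derive_mode_writes_all_outputs(self, tmp_path):
        write_inputs(tmp_path)
        cfg = PipelineConfig(
            expression=str(tmp_path / "expression.tsv"),
            housekeeping=str(tmp_path / "housekeeping.txt"),
            annotation=str(tmp_path / "annotation.csv"),
            gene_sets=str(tmp_path / "gene_sets.gmt"),
            outdir=str(tmp_path / "out"),
            n_permutations=200,
            seed=4,
        )
        manifest = run_pipeline(cfg)
        assert manifest["failed_stage"] is None
        for name in ("normalized.tsv", "cell_scores.csv", "enrichment.csv",
                     "signature.tsv", "scores.csv", "survival_km.csv",
                     "survival_summary.csv", "manifest.json", "summary.txt"):
            assert (tmp_path / "out" / name).exists() or name == "manifest.json"
        assert (tmp_path / "out" / "manifest.json").exists()

    def test_rerun_reproduces_outputs_byte_identically(self, tmp_path):
        write_inputs(tmp_path, seed=6)
        common = dict(
            expression=str(tmp_path / "expression.tsv"),
            housekeeping=str(tmp_path / "housekeeping.txt"),
            annotation=str(tmp_path / "annotation.csv"),
            gene_sets=str(tmp_path / "gene_sets.gmt"),
            n_permutations=150,
            seed=8,
        )
        m1 = run_pipeline(PipelineConfig(outdir=str(tmp_path / "o1"), **common))
        run_pipeline(PipelineConfig(outdir=str(tmp_path / "o2"), **common))
        for name in m1["outputs"]:
            a = (tmp_path / "o1" / name).read_bytes()
            b = (tmp_path / "o2" / name).read_bytes()
            assert a == b, name

    def test_apply_mode_with_frozen_signature(self, tmp_path):
        write_inputs(tmp_path, n_samples=26, seed=9)
        cfg = PipelineConfig(
            expression=str(tmp_path / "expression.tsv"),
            housekeeping=str(tmp_path / "housekeeping.txt"),
            annotation=str(tmp_path / "annotation.csv"),
            outdir=str(tmp_path / "out"),
            mode="apply",
        )
        manifest = run_pipeline(cfg)
        assert "response_roc_summary.csv" in manifest["outputs"]

    def test_apply_mode_missing_gene_fails_with_marker(self, tmp_path):
        cohort = generate_cohort(SynthConfig(n_samples=10, seed=2,
                                             include_marker_genes=False))
        cohort.write(tmp_path)
        cfg = PipelineConfig(
            expression=str(tmp_path / "expression.tsv"),
            housekeeping=str(tmp_path / "housekeeping.txt"),
            annotation=str(tmp_path / "annotation.csv"),
            outdir=str(tmp_path / "out"),
            mode="apply",
        )
        with pytest.raises(MissingGeneError, match="LAG3"):
            run_pipeline(cfg)
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["failed_stage"] == "apply"

    def test_derive_then_apply_orders_validation_medians(self):
        """Protective planted hazard: high-score stratum outlives low-score
        in most independent validation cohorts."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg, coll = make_signature_scenario(n_samples=30, seed=100 + seed)
            train = generate_cohort(cfg)
            res = SignatureDiscovery(train.expression, train.annotation, coll,
                                     n_permutations=200).fit(seed=seed)
            cfg2, _ = make_signature_scenario(n_samples=26, seed=900 + seed)
            test = generate_cohort(cfg2)
            v = res.apply(test.expression, test.annotation)
            med_high = v.survival.medians["high"]
            med_low = v.survival.medians["low"]
            wins += (np.isnan(med_high) and not np.isnan(med_low)) or (
                med_high > med_low
            )
        assert wins >= int(0.8 * n_seeds)


class TestCli:
    def test_simulate_normalize_score_chain(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "simulate", "--outdir", str(tmp_path), "--n-samples", "12",
            "--seed", "1", "--scenario",
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "normalize", "--expression", str(tmp_path / "expression.tsv"),
            "--housekeeping", str(tmp_path / "housekeeping.txt"),
            "--out", str(tmp_path / "norm.tsv"),
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "score", "--expression", str(tmp_path / "expression.tsv"),
            "--housekeeping", str(tmp_path / "housekeeping.txt"),
            "--out", str(tmp_path / "scores.csv"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "scores.csv").exists()

    def test_run_all_derive(self, tmp_path):
        runner = CliRunner()
        runner.invoke(cli_main, [
            "simulate", "--outdir", str(tmp_path), "--n-samples", "20",
            "--seed", "2", "--scenario",
        ])
        r = runner.invoke(cli_main, [
            "run-all",
            "--expression", str(tmp_path / "expression.tsv"),
            "--housekeeping", str(tmp_path / "housekeeping.txt"),
            "--annotation", str(tmp_path / "annotation.csv"),
            "--gene-sets", str(tmp_path / "gene_sets.gmt"),
            "--n-perm", "150", "--seed", "3",
            "--outdir", str(tmp_path / "out"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "out" / "signature.tsv").exists()

    def test_tmb_subcommand(self, tmp_path):
        from immunosig.simulate import generate_variant_table

        table = generate_variant_table(6, {"missense": 2.0, "synonymous": 1.0},
                                       seed=0)
        table.to_csv(tmp_path / "variants.tsv", sep="\t", index=False)
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "tmb", "--variants", str(tmp_path / "variants.tsv"),
            "--panel-mb", "1.5", "--out", str(tmp_path / "tmb.csv"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "tmb.csv").exists()
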