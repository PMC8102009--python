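"""TSA-TWAS router: threshold arithmetic, gene classification, allele
alignment, the applied pipeline on simulated truth, and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from tsatwas import (
    AppliedStudy,
    GroupLassoWeights,
    ScenarioConfig,
    ThresholdSpec,
    bonferroni_threshold,
    classify_genes,
    run_tsa_twas,
    simulate_gene_trait_pair,
    weights_to_table,
)
from tsatwas.cli import main
from tsatwas.exceptions import ParameterError, StructuralError
from tsatwas.tsa import _align_weights, read_dosages_tsv


class TestThresholds:
    @pytest.mark.parametrize("genes,traits,expected,digits", [
        (12038, 37, 1.12e-7, 3),  # family-wise across both methods
        (9226, 37, 1.46e-7, 3),   # method-wise, cross-tissue genes
        (2812, 37, 4.8e-7, 2),    # method-wise, single-tissue genes
    ])
    def test_printed_threshold_arithmetic(self, genes, traits, expected, digits):
        v = bonferroni_threshold(ThresholdSpec(alpha=0.05, n_genes=genes,
                                               n_traits=traits))
        # agreement at the printed precision
        assert float(f"%.{digits - 1}e" % v) == pytest.approx(expected, rel=1e-12)

    def test_identity_threshold(self):
        assert bonferroni_threshold(ThresholdSpec(alpha=0.05)) == 0.05

    def test_zero_denominator_rejected(self):
        with pytest.raises(ParameterError):
            ThresholdSpec(n_genes=0)

    def test_family_wise_not_looser_than_method_wise(self):
        fam = bonferroni_threshold(ThresholdSpec(n_genes=12038, n_traits=37))
        meth = bonferroni_threshold(ThresholdSpec(n_genes=9226, n_traits=37))
        assert fam <= meth


class TestClassification:
    def test_routes_and_exclusions(self):
        w = pd.DataFrame({
            "gene_id": ["g1", "g2", "g2", "g3"],
            "snp_id": ["s1", "s2", "s3", "s4"],
            "ref": "A", "alt": "G",
            "tissue": ["liver", "liver", "brain", "liver"],
            "weight": [0.5, 0.1, -0.2, 0.0],
        })
        table, excluded = classify_genes(w)
        routes = dict(zip(table["gene_id"], table["route"]))
        assert routes == {"g1": "slr", "g2": "gbj"}
        assert list(excluded["gene_id"]) == ["g3"]

    def test_many_tissue_gene_routed_cross(self):
        w = pd.DataFrame({
            "gene_id": "g", "snp_id": [f"s{i}" for i in range(49)],
            "ref": "A", "alt": "G",
            "tissue": [f"t{i}" for i in range(49)], "weight": 0.1,
        })
        table, _ = classify_genes(w)
        assert table["route"].iloc[0] == "gbj"
        assert table["n_tissues"].iloc[0] == 49


class TestAlleleAlignment:
    def _dosages(self):
        return pd.DataFrame({"ref": ["A", "C", "A", "G"], "alt": ["G", "T", "T", "C"],
                             "s1": [0.0] * 4}, index=["snp1", "snp2", "snp3", "snp4"])

    def test_exact_swap_complement_and_ambiguous(self):
        w = pd.DataFrame({
            "snp_id": ["snp1", "snp1", "snp2", "snp3", "snp4", "snp9"],
            "ref": ["A", "G", "G", "T", "G", "A"],
            "alt": ["G", "A", "A", "A", "C", "G"],
            "weight": [1.0] * 6,
        })
        kept, signs, dropped = _align_weights(w, self._dosages())
        # snp1 exact (+), snp1 swapped (-), snp2 strand complement G/A -> C/T (+),
        # snp3 palindromic A/T dropped, snp4 exact (+), snp9 missing
        assert kept == ["snp1", "snp1", "snp2", "snp4"]
        np.testing.assert_array_equal(signs, [1.0, -1.0, 1.0, 1.0])
        assert dropped == {"missing": 1, "allele_mismatch": 0, "ambiguous_strand": 1}


@pytest.fixture(scope="module")
def applied_study(tmp_path_factory):
    """Applied study built from simulated truth: gene0 is causal (r2=5%)."""
    cfg = ScenarioConfig(n_tissues=3, m_mt=10, m_eqtl=15, m_null=10,
                         cor_tissue=0.6, r2_expr_trait=0.05,
                         n_total=900, n_eqtl_train=300, n_twas=600, seed=55)
    weights_all, dosage_rows, trait = [], [], None
    for gidx in range(5):
        panel, eff, expr, tv = simulate_gene_trait_pair(cfg, 0, gidx)
        xs = panel.standardized
        gl = GroupLassoWeights(random_state=1, n_alphas=16, alpha_eps=3e-2, cv=3,
                               compute_cv_score=False)
        gl.fit(xs[panel.train_rows], expr.expression[panel.train_rows])
        snp_ids = [f"g{gidx}_snp{i}" for i in range(panel.n_snps)]
        weights_all.append(weights_to_table(gl, f"gene{gidx}", snp_ids))
        dos = pd.DataFrame(xs[panel.twas_rows].T, index=snp_ids,
                           columns=[f"s{i}" for i in range(cfg.n_twas)])
        dos.insert(0, "ref", "A")
        dos.insert(1, "alt", "G")
        dosage_rows.append(dos)
        if gidx == 0:
            trait = tv
    weights = pd.concat(weights_all, ignore_index=True)
    dosages = pd.concat(dosage_rows)
    dosages.index.name = "snp_id"
    pheno = pd.DataFrame({"trait1": trait.y},
                         index=[f"s{i}" for i in range(cfg.n_twas)])
    return AppliedStudy(weights=weights, dosages=dosages, phenotypes=pheno)


class TestAppliedPipeline:
    def test_causal_gene_tracked_end_to_end(self, applied_study):
        res = run_tsa_twas(applied_study, [ThresholdSpec(n_genes=5, name="study")],
                           seed=3)
        assert len(res) == 5
        best = res.sort_values("p_value").iloc[0]
        assert best["gene_id"] == "gene0"
        assert best["p_value"] < 0.05 / 5
        # non-causal genes are not significant at the study threshold
        others = res[res["gene_id"] != "gene0"]
        assert (others["p_value"] > bonferroni_threshold(
            ThresholdSpec(n_genes=5))).all()

    def test_duplicate_trait_columns_identical(self, applied_study):
        study = AppliedStudy(weights=applied_study.weights,
                             dosages=applied_study.dosages,
                             phenotypes=applied_study.phenotypes.assign(
                                 trait2=applied_study.phenotypes["trait1"]))
        res = run_tsa_twas(study, seed=3)
        a = res[res["trait"] == "trait1"].set_index("gene_id")["p_value"]
        b = res[res["trait"] == "trait2"].set_index("gene_id")["p_value"]
        pd.testing.assert_series_equal(a, b, check_names=False)

    def test_single_tissue_weights_route_to_slr(self, applied_study):
        w = applied_study.weights
        liver_only = w[w["tissue"] == w["tissue"].unique()[0]]
        study = AppliedStudy(weights=liver_only, dosages=applied_study.dosages,
                             phenotypes=applied_study.phenotypes)
        res = run_tsa_twas(study, seed=3)
        assert (res["method"] == "slr").all()

    def test_missing_sample_raises(self, applied_study):
        pheno = applied_study.phenotypes.copy()
        pheno.index = ["nobody"] * len(pheno)
        study = AppliedStudy(weights=applied_study.weights,
                             dosages=applied_study.dosages, phenotypes=pheno)
        with pytest.raises(StructuralError):
            run_tsa_twas(study)


class TestCli:
    def test_simulate_and_run_round_trip(self, tmp_path, applied_study):
        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(main, ["simulate", "--seed", "4", "--n-tissues", "2",
                                 "--m-mt", "5", "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "dosages.tsv").exists()
        assert (out / "params.json").exists()

        # applied mode from flat files
        wpath = tmp_path / "w.tsv"
        dpath = tmp_path / "d.tsv"
        ppath = tmp_path / "p.tsv"
        applied_study.weights.to_csv(wpath, sep="\t", index=False)
        applied_study.dosages.reset_index().to_csv(dpath, sep="\t", index=False)
        applied_study.phenotypes.rename_axis("sample").to_csv(ppath, sep="\t")
        rpath = tmp_path / "res.tsv"
        r = runner.invoke(main, ["run", "--weights", str(wpath), "--dosages",
                                 str(dpath), "--pheno", str(ppath), "--out",
                                 str(rpath), "--seed", "1"])
        assert r.exit_code == 0, r.output
        res = pd.read_csv(rpath, sep="\t")
        assert {"gene_id", "method", "p_value"} <= set(res.columns)
        assert rpath.with_suffix(".provenance.json").exists()

    def test_grid_and_heritability_commands(self, tmp_path):
        runner = CliRunner()
        cfgfile = tmp_path / "grid.yaml"
        cfgfile.write_text(
            "n_tissues: [1, 2]\nm_mt: 0\nm_eqtl: 10\nm_null: 8\n"
            "r2_expr_trait: 0.05\nn_total: 300\nn_eqtl_train: 100\nn_twas: 200\n"
            "n_pairs: 3\nn_reps: 1\n")
        out = tmp_path / "perf.tsv"
        r = runner.invoke(main, ["grid", "--config", str(cfgfile), "--seed", "2",
                                 "--methods", "elastic_net:slr", "--out", str(out)])
        assert r.exit_code == 0, r.output
        perf = pd.read_csv(out, sep="\t")
        assert set(perf["n_tissues"]) == {1, 2}

        hout = tmp_path / "h2.tsv"
        r = runner.invoke(main, ["heritability", "--seed", "3",
                                 "--n-individuals", "300", "--n-traits", "2",
                                 "--n-geno-reps", "2", "--out", str(hout)])
        assert r.exit_code == 0, r.output
        assert hout.exists()


def test_dosage_reader_requires_columns(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("snp_id\tref\ts1\nsnp1\tA\t0.5\n")
    with pytest.raises(StructuralError):
        read_dosages_tsv(bad)
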